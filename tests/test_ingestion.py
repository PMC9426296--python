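"""Radiocesium ingestion: intake function, two intake periods, dose integral."""

import datetime as dt
import math

import numpy as np
import pytest

from doserecon.core import ACCIDENT_DATE, ExposureWindow, Sex, WindowKind
from doserecon.ingestion import (
    CS134_RATIO,
    DEFAULT_DF,
    DietRecord,
    IntakeParams,
    PERIOD_BOUNDARY_DAY,
    cf_spec,
    ingestion_dose,
    intake_function,
    milk_concentration,
)
from doserecon.resexternal import ResidenceRecord, SettlementRecord

SETTLEMENT = SettlementRecord(id="s", country="Ukraine", cs137_kbq_m2=200.0)


def _window(days):
    return ExposureWindow(
        end=ACCIDENT_DATE + dt.timedelta(days=days), kind=WindowKind.DOB38
    )


def _record(days):
    return ResidenceRecord(
        parent_id="p", settlement_id="s", start=ACCIDENT_DATE,
        end=ACCIDENT_DATE + dt.timedelta(days=days),
    )


def _diet(**rates):
    return DietRecord(parent_id="p", rates=rates)


class TestIntakeFunction:
    def test_zero_consumption_gives_zero(self):
        out = intake_function(dt.date(1986, 6, 1), _diet(), IntakeParams())
        assert out == {"Cs-134": 0.0, "Cs-137": 0.0}

    def test_linearity_in_consumption_rates(self):
        params = IntakeParams()
        t = dt.date(1986, 6, 1)
        base = intake_function(t, _diet(milk=0.3, meat=0.1), params)
        double = intake_function(t, _diet(milk=0.6, meat=0.2), params)
        for k in base:
            assert double[k] == pytest.approx(2 * base[k], rel=1e-12)

    def test_mushroom_vs_potato_conversion_factor_ratio(self):
        # mushrooms concentrate cesium U(5,15); potatoes U(0.12,0.24)
        params = IntakeParams()
        t = dt.date(1987, 6, 1)  # root-uptake period: both foods contribute
        mush = intake_function(t, _diet(mushrooms=0.02), params)["Cs-137"]
        pot = intake_function(t, _diet(potatoes=0.02), params)["Cs-137"]
        assert 5 / 0.24 <= mush / pot <= 15 / 0.12

    def test_period1_excludes_root_uptake_foods(self):
        params = IntakeParams()
        t = dt.date(1986, 6, 1)  # pasture period
        out = intake_function(t, _diet(potatoes=1.0, mushrooms=0.02), params)
        assert out["Cs-137"] == 0.0

    def test_date_before_accident_rejected(self):
        with pytest.raises(ValueError):
            intake_function(dt.date(1986, 1, 1), _diet(milk=0.3), IntakeParams())


class TestMilkConcentration:
    def test_period_boundary_switches_curves(self):
        params = IntakeParams()
        before = float(milk_concentration(PERIOD_BOUNDARY_DAY - 1, "Cs-137", params))
        after = float(milk_concentration(PERIOD_BOUNDARY_DAY, "Cs-137", params))
        # period 1 decays from c86_am; period 2 starts at the transfer factor
        assert before == pytest.approx(
            params.c86_am * math.exp(-math.log(2) / 14.0 * (PERIOD_BOUNDARY_DAY - 1))
        )
        assert after == pytest.approx(params.tf_am)

    def test_cs134_tracks_cs137_with_ratio_and_decay(self):
        params = IntakeParams()
        d = 50
        c137 = float(milk_concentration(d, "Cs-137", params))
        c134 = float(milk_concentration(d, "Cs-134", params))
        lam134 = math.log(2) / (2.065 * 365.25)
        lam137 = math.log(2) / (30.05 * 365.25)
        assert c134 / c137 == pytest.approx(
            CS134_RATIO * math.exp(-(lam134 - lam137) * d), rel=1e-9
        )


class TestIngestionDose:
    def test_zero_deposition(self):
        got = ingestion_dose(
            _record(100), _diet(milk=0.5), SETTLEMENT, IntakeParams(),
            _window(200), Sex.MALE, sigma=0.0,
        )
        assert float(got) == 0.0

    def test_window_before_residence_gives_zero(self):
        rec = ResidenceRecord(
            parent_id="p", settlement_id="s",
            start=ACCIDENT_DATE + dt.timedelta(days=400),
            end=ACCIDENT_DATE + dt.timedelta(days=500),
        )
        got = ingestion_dose(
            rec, _diet(milk=0.5), SETTLEMENT, IntakeParams(), _window(100), Sex.MALE
        )
        assert float(got) == 0.0

    def test_piecewise_constant_curve_matches_rectangle_oracle(self):
        # constant normalized concentration c over 100 pasture-period days:
        # dose = sigma * sum_k DF_k * rate * CF * sum_d c_k(d), hand-computed
        c = 2.5
        params = IntakeParams(curve1_table=np.full(400, c))
        diet = _diet(milk=0.4)
        days = 90  # stays within period 1
        got = float(
            ingestion_dose(
                diet and _record(days), diet, SETTLEMENT, params, _window(days),
                Sex.MALE,
            )
        )
        lam134 = math.log(2) / (2.065 * 365.25)
        lam137 = math.log(2) / (30.05 * 365.25)
        s137 = c * days
        s134 = c * sum(
            CS134_RATIO * math.exp(-(lam134 - lam137) * d) for d in range(days)
        )
        expected = SETTLEMENT.cs137_kbq_m2 * 0.4 * 1.0 * (
            DEFAULT_DF["Cs-137"]["male"] * s137 + DEFAULT_DF["Cs-134"]["male"] * s134
        )
        assert got == pytest.approx(expected, rel=1e-9)

    def test_split_at_period_boundary_equals_whole(self):
        params = IntakeParams()
        diet = _diet(milk=0.4, potatoes=0.3)
        whole = float(
            ingestion_dose(
                _record(400), diet, SETTLEMENT, params, _window(400), Sex.MALE
            )
        )
        rec1 = ResidenceRecord(
            parent_id="p", settlement_id="s", start=ACCIDENT_DATE,
            end=ACCIDENT_DATE + dt.timedelta(days=PERIOD_BOUNDARY_DAY),
        )
        rec2 = ResidenceRecord(
            parent_id="p", settlement_id="s",
            start=ACCIDENT_DATE + dt.timedelta(days=PERIOD_BOUNDARY_DAY),
            end=ACCIDENT_DATE + dt.timedelta(days=400),
        )
        split = float(
            ingestion_dose(rec1, diet, SETTLEMENT, params, _window(400), Sex.MALE)
        ) + float(
            ingestion_dose(rec2, diet, SETTLEMENT, params, _window(400), Sex.MALE)
        )
        assert whole == pytest.approx(split, rel=1e-12)

    def test_isotope_doses_sum_to_total(self):
        params = IntakeParams()
        diet = _diet(milk=0.4, meat=0.2)
        kwargs = dict(
            record=_record(300), diet=diet, settlement=SETTLEMENT, params=params,
            window=_window(300), sex=Sex.MALE,
        )
        total = float(ingestion_dose(**kwargs))
        df0 = {k: {"male": 0.0, "female": 0.0} for k in DEFAULT_DF}
        only = {}
        for k in DEFAULT_DF:
            df = {
                iso: (DEFAULT_DF[iso]["male"] if iso == k else 0.0)
                for iso in DEFAULT_DF
            }
            only[k] = float(ingestion_dose(**kwargs, df=df))
        assert total == pytest.approx(only["Cs-134"] + only["Cs-137"], rel=1e-12)

    def test_linearity_in_sigma_and_rates(self):
        params = IntakeParams()
        base = float(
            ingestion_dose(
                _record(200), _diet(milk=0.3), SETTLEMENT, params, _window(200),
                Sex.MALE, sigma=100.0,
            )
        )
        assert float(
            ingestion_dose(
                _record(200), _diet(milk=0.3), SETTLEMENT, params, _window(200),
                Sex.MALE, sigma=200.0,
            )
        ) == pytest.approx(2 * base, rel=1e-12)
        assert float(
            ingestion_dose(
                _record(200), _diet(milk=0.6), SETTLEMENT, params, _window(200),
                Sex.MALE, sigma=100.0,
            )
        ) == pytest.approx(2 * base, rel=1e-12)

    def test_missing_diet_warns_and_returns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            got = ingestion_dose(
                _record(100), None, SETTLEMENT, IntakeParams(), _window(100), Sex.MALE
            )
        assert float(got) == 0.0
        assert any("diet" in r.message for r in caplog.records)

    def test_wbc_derived_dose_passthrough(self):
        rec = ResidenceRecord(
            parent_id="p", settlement_id="s", start=ACCIDENT_DATE,
            end=ACCIDENT_DATE + dt.timedelta(days=100), wbc_ingestion_mgy=1.7,
        )
        got = ingestion_dose(
            rec, _diet(milk=0.5), SETTLEMENT, IntakeParams(), _window(50), Sex.MALE
        )
        assert float(got) == 1.7


class TestConversionFactors:
    @pytest.mark.parametrize(
        "food, lo, hi",
        [
            ("milk_products", 0.5, 0.9),
            ("meat", 0.8, 1.0),
            ("potatoes", 0.12, 0.24),
            ("mushrooms", 5.0, 15.0),
        ],
    )
    def test_uniform_ranges(self, food, lo, hi):
        spec = cf_spec(food)
        assert (spec.params["min"], spec.params["max"]) == (lo, hi)

    def test_local_milk_is_reference(self):
        assert cf_spec("milk", "local").central() == 1.0
        shop = cf_spec("milk", "shop")
        assert (shop.params["min"], shop.params["max"]) == (0.9, 1.0)
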