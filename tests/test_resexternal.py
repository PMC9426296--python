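"""Residential ground-shine: decay chains, attenuation and the dose integral."""

import datetime as dt
import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from doserecon.core import ACCIDENT_DATE, ExposureWindow, Sex, WindowKind
from doserecon.nuclides import default_inventory, load_inventory
from doserecon.resexternal import (
    AttenuationParams,
    ResidenceRecord,
    SettlementRecord,
    attenuation,
    behaviour_factor_spec,
    deposition_activity,
    deposition_spec,
    nuclide_dose_integral,
    residential_external_dose,
)

INV = default_inventory()
RATIOS = {name: rec.ratio_spec.central() for name, rec in INV.items()}
NO_ATTEN = AttenuationParams(p1=0.4, lambda1=0.0, lambda2=0.0)  # p(t) = 1


def _window(days):
    return ExposureWindow(
        end=ACCIDENT_DATE + dt.timedelta(days=days), kind=WindowKind.DOB38
    )


def _record(days, house="wooden"):
    return ResidenceRecord(
        parent_id="p", settlement_id="s", start=ACCIDENT_DATE,
        end=ACCIDENT_DATE + dt.timedelta(days=days), house_type=house,
    )


SETTLEMENT = SettlementRecord(id="s", country="Ukraine", cs137_kbq_m2=100.0)


class TestDepositionActivity:
    def test_no_decay_at_time_zero(self):
        for name in ("Cs-137", "I-131", "La-140"):
            got = deposition_activity(INV[name], 0.0, 50.0, RATIOS, INV)
            assert got == pytest.approx(50.0 * RATIOS[name])

    def test_one_half_life_halves_chain_free_nuclide(self):
        rec = INV["I-131"]
        t_half = math.log(2) / rec.decay_const
        got = deposition_activity(rec, t_half, 10.0, RATIOS, INV)
        assert got == pytest.approx(10.0 * RATIOS["I-131"] / 2, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            deposition_activity(INV["Cs-137"], -1.0, 1.0, RATIOS, INV)

    def test_bateman_daughter_matches_ode_oracle(self):
        # Ba-140 -> La-140 with unit initial areal activities, t = 10 d:
        # integrate the activity system dA_p/dt = -lp Ap,
        # dA_d/dt = ld/lp * (-lp Ap)... in activity units:
        # A_d' = ld*(Ap*ld/lp? ) -- work in atom numbers N and convert.
        lp = INV["Ba-140"].decay_const
        ld = INV["La-140"].decay_const
        ratios = dict(RATIOS)
        ratios["Ba-140"] = 1.0
        ratios["La-140"] = 1.0

        def rhs(t, y):
            n_p, n_d = y
            return [-lp * n_p, lp * n_p - ld * n_d]

        # unit activities -> atom numbers 1/lambda
        sol = solve_ivp(
            rhs, (0, 10.0), [1 / lp, 1 / ld], rtol=1e-10, atol=1e-14,
            dense_output=True,
        )
        expected_activity = ld * sol.y[1, -1]
        got = deposition_activity(INV["La-140"], 10.0, 1.0, ratios, INV)
        assert got == pytest.approx(expected_activity, rel=1e-3)

    def test_zero_parent_ratio_reduces_daughter_to_pure_decay(self):
        ratios = dict(RATIOS)
        ratios["Te-132"] = 0.0
        rec = INV["I-132"]
        got = deposition_activity(rec, 0.2, 1.0, ratios, INV)
        assert got == pytest.approx(
            RATIOS["I-132"] * math.exp(-rec.decay_const * 0.2), rel=1e-12
        )


class TestAttenuation:
    def test_normalized_at_zero(self):
        assert attenuation(0.0, AttenuationParams()) == pytest.approx(1.0)

    def test_central_value_at_1000_days(self):
        # 0.4 e^-1.27 + 0.6 e^-0.038, independent arithmetic check
        expected = 0.4 * math.exp(-1.27) + 0.6 * math.exp(-0.038)
        assert attenuation(1000.0, AttenuationParams()) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.690, abs=0.001)

    def test_vanishes_at_infinity(self):
        assert attenuation(1e7, AttenuationParams()) < 1e-10

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            attenuation(-1.0, AttenuationParams())


class TestDoseIntegral:
    def test_single_exponential_closed_form(self):
        # sigma * R * (1 - e^{-lam dt}) / lam for Cs-137 with p == 1
        rec = INV["Cs-137"]
        lam = rec.decay_const
        got = nuclide_dose_integral(rec, 0.0, 365.0, RATIOS, None, INV)
        expected = RATIOS["Cs-137"] * (1 - math.exp(-lam * 365.0)) / lam
        assert float(got) == pytest.approx(expected, rel=1e-12)

    def test_analytic_vs_adaptive_quadrature(self):
        for name in ("Cs-137", "I-131", "La-140", "Nb-95"):
            atten = AttenuationParams() if name == "Cs-137" else None
            a = float(nuclide_dose_integral(INV[name], 3.0, 200.0, RATIOS, atten, INV))
            q = float(
                nuclide_dose_integral(
                    INV[name], 3.0, 200.0, RATIOS, atten, INV, method="quad"
                )
            )
            assert a == pytest.approx(q, rel=1e-6)

    def test_split_at_boundary_equals_whole(self):
        rec = INV["Cs-137"]
        whole = float(
            nuclide_dose_integral(rec, 0.0, 400.0, RATIOS, AttenuationParams(), INV)
        )
        split = float(
            nuclide_dose_integral(rec, 0.0, 97.0, RATIOS, AttenuationParams(), INV)
        ) + float(
            nuclide_dose_integral(rec, 97.0, 400.0, RATIOS, AttenuationParams(), INV)
        )
        assert whole == pytest.approx(split, rel=1e-8)


class TestResidentialDose:
    def test_zero_deposition_gives_zero(self):
        got = residential_external_dose(
            _record(100), SettlementRecord(id="s", country="Ukraine", cs137_kbq_m2=0.0),
            _window(200), Sex.MALE, sigma=0.0,
        )
        assert float(got) == 0.0

    def test_single_nuclide_closed_form(self):
        inv = {"Cs-137": INV["Cs-137"]}
        lam = INV["Cs-137"].decay_const
        dc = INV["Cs-137"].dc_for(Sex.MALE)
        bf, iv, sigma, days = 0.28, 1.1, 100.0, 365
        got = residential_external_dose(
            _record(days), SETTLEMENT, _window(days), Sex.MALE,
            sigma=sigma, bf=bf, iv=iv, atten=NO_ATTEN, inventory=inv,
        )
        expected = bf * iv * dc * sigma * (1 - math.exp(-lam * days)) / lam
        assert float(got) == pytest.approx(expected, rel=1e-6)

    def test_full_inventory_equals_sum_of_singles(self):
        whole = residential_external_dose(
            _record(30), SETTLEMENT, _window(30), Sex.MALE, inventory=INV
        )
        parts = sum(
            float(
                residential_external_dose(
                    _record(30), SETTLEMENT, _window(30), Sex.MALE,
                    inventory={name: INV[name]},
                )
            )
            for name in INV
        )
        assert float(whole) == pytest.approx(parts, rel=1e-10)

    def test_linearity_in_sigma(self):
        d1 = residential_external_dose(
            _record(60), SETTLEMENT, _window(60), Sex.MALE, sigma=50.0
        )
        d2 = residential_external_dose(
            _record(60), SETTLEMENT, _window(60), Sex.MALE, sigma=100.0
        )
        assert float(d2) == pytest.approx(2 * float(d1), rel=1e-12)

    def test_monotone_in_iv_bf_and_window(self):
        base = float(
            residential_external_dose(
                _record(300), SETTLEMENT, _window(100), Sex.MALE, iv=1.0, bf=0.2
            )
        )
        assert float(
            residential_external_dose(
                _record(300), SETTLEMENT, _window(100), Sex.MALE, iv=1.3, bf=0.2
            )
        ) >= base
        assert float(
            residential_external_dose(
                _record(300), SETTLEMENT, _window(100), Sex.MALE, iv=1.0, bf=0.3
            )
        ) >= base
        assert float(
            residential_external_dose(
                _record(300), SETTLEMENT, _window(200), Sex.MALE, iv=1.0, bf=0.2
            )
        ) >= base

    def test_empty_intersection_gives_zero(self):
        rec = ResidenceRecord(
            parent_id="p", settlement_id="s",
            start=ACCIDENT_DATE + dt.timedelta(days=500),
            end=ACCIDENT_DATE + dt.timedelta(days=600),
        )
        assert float(
            residential_external_dose(rec, SETTLEMENT, _window(100), Sex.MALE)
        ) == 0.0

    def test_unknown_house_type_rejected(self):
        with pytest.raises(ValueError):
            ResidenceRecord(
                parent_id="p", settlement_id="s", start=ACCIDENT_DATE,
                end=ACCIDENT_DATE + dt.timedelta(days=10), house_type="yurt",
            )


class TestSpecs:
    def test_behaviour_factor_centrals(self):
        assert behaviour_factor_spec("wooden", "30km").central() == pytest.approx(0.34)
        assert behaviour_factor_spec("wooden", "other").central() == pytest.approx(0.28)
        assert behaviour_factor_spec("brick_multi_floor", "other").central() == pytest.approx(0.13)

    def test_deposition_spec_families(self):
        ua = deposition_spec(100.0, "Ukraine")
        assert ua.params["gm"] == pytest.approx(96.0)
        assert ua.params["gsd"] == 1.4
        by_hi = deposition_spec(200.0, "Belarus")
        assert by_hi.params["gsd"] == 1.6  # above the 185 kBq/m2 split
        by_lo = deposition_spec(100.0, "Belarus")
        assert by_lo.params["gsd"] == 1.4

    def test_inventory_override_round_trip(self, tmp_path):
        cfg = tmp_path / "nuc.json"
        cfg.write_text('{"Cs-137": {"half_life_days": 11000.0, "ratio": 1.0}}')
        inv = load_inventory(cfg)
        assert inv["Cs-137"].half_life_days == pytest.approx(11000.0)
        assert inv["I-131"].decay_const == INV["I-131"].decay_const
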