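"""Time-and-motion external dose kernels (cleanup mission and Pripyat)."""

import datetime as dt

import numpy as np
import pytest

from doserecon.core import ACCIDENT_DATE, WindowKind
from doserecon.distributions import (
    RngStream,
    am_from_gm_gsd,
    empirical_gsd,
    point,
    trunclognorm,
)
from doserecon.mission import (
    AkrGrid,
    ItineraryEntry,
    PripyatEntry,
    daily_average_lf,
    mission_dose_deterministic,
    mission_dose_stochastic,
    pripyat_dose,
    pripyat_dose_deterministic,
)

FAR = dt.date(2010, 1, 1)


def _entry(day, loc="L0", hours=1.0, lf=1.0):
    return ItineraryEntry(
        day=day, location_id=loc, activity="work",
        duration=point(hours), lf=point(lf),
    )


class TestDailyAverageLf:
    @pytest.mark.parametrize(
        "day, night, expected_2sf",
        [(0.072, 0.0018, 0.049), (0.038, 0.0001, 0.025)],
    )
    def test_printed_floor_values(self, day, night, expected_2sf):
        # 16 h at the daytime LF, 8 h at the sleeping-area LF
        got = daily_average_lf(day, night, 8.0)
        assert float(f"{got:.2g}") == expected_2sf

    def test_identical_day_night(self):
        assert daily_average_lf(0.3, 0.3, 5.0) == pytest.approx(0.3)

    def test_bad_sleep_hours(self):
        with pytest.raises(ValueError):
            daily_average_lf(0.1, 0.1, 25)


class TestMissionDeterministic:
    def test_empty_itinerary(self, unit_grid):
        assert mission_dose_deterministic([], unit_grid, 0.710, FAR) == 0.0

    def test_single_unit_entry_male(self, unit_entry, unit_grid):
        dose = mission_dose_deterministic([unit_entry], unit_grid, 0.710, FAR)
        assert dose == pytest.approx(0.710)

    def test_three_entry_sum_matches_term_by_term_oracle(self):
        grid = AkrGrid()
        rates = {"A": 0.5, "B": 2.0, "C": 1.3}
        for loc, r in rates.items():
            grid.add(loc, ACCIDENT_DATE, point(r))
        entries = [
            _entry(dt.date(1986, 5, 1), "A", hours=2.0, lf=0.9),
            _entry(dt.date(1986, 5, 2), "B", hours=1.5, lf=0.4),
            _entry(dt.date(1986, 5, 3), "C", hours=8.0, lf=1.1),
        ]
        oracle = 0.710 * sum(
            rates[e.location_id] * e.duration.central() * e.lf.central()
            for e in entries
        )
        assert mission_dose_deterministic(entries, grid, 0.710, FAR) == pytest.approx(
            oracle, rel=1e-12
        )

    def test_unresolved_location_names_entry(self, unit_entry):
        with pytest.raises(KeyError, match="L0"):
            mission_dose_deterministic([unit_entry], AkrGrid(), 0.710, FAR)

    def test_cutoff_excludes_entries_on_and_after(self, unit_grid):
        entries = [_entry(dt.date(1986, 6, d)) for d in (1, 2, 3)]
        dose = mission_dose_deterministic(entries, unit_grid, 1.0, dt.date(1986, 6, 2))
        assert dose == pytest.approx(1.0)  # only the 1 June entry counts

    def test_linearity_in_durations(self, unit_grid):
        e1 = [_entry(dt.date(1986, 6, 1), hours=h) for h in (1.0, 2.0)]
        e3 = [_entry(dt.date(1986, 6, 1), hours=3 * h) for h in (1.0, 2.0)]
        d1 = mission_dose_deterministic(e1, unit_grid, 0.7, FAR)
        d3 = mission_dose_deterministic(e3, unit_grid, 0.7, FAR)
        assert d3 == pytest.approx(3 * d1)

    def test_additivity_over_partition(self, unit_grid):
        entries = [_entry(dt.date(1986, 6, d), hours=d) for d in range(1, 6)]
        whole = mission_dose_deterministic(entries, unit_grid, 0.7, FAR)
        parts = mission_dose_deterministic(
            entries[:2], unit_grid, 0.7, FAR
        ) + mission_dose_deterministic(entries[2:], unit_grid, 0.7, FAR)
        assert whole == pytest.approx(parts)

    def test_cutoff_monotonicity(self, unit_grid):
        entries = [_entry(dt.date(1986, 6, d)) for d in range(1, 20)]
        doses = [
            mission_dose_deterministic(
                entries, unit_grid, 0.7, dt.date(1986, 6, 1) + dt.timedelta(days=k)
            )
            for k in range(0, 25, 5)
        ]
        assert all(b >= a for a, b in zip(doses, doses[1:]))


class TestMissionStochastic:
    def test_degenerate_specs_reproduce_deterministic(self, unit_entry, unit_grid):
        doses = mission_dose_stochastic(
            [unit_entry], unit_grid, point(0.710), FAR, n=50,
            stream=RngStream(1), subject_id="p1",
        )
        np.testing.assert_allclose(doses.values, 0.710)

    def test_one_factor_tln_gsd_recovery(self):
        # dose = const * AKR with AKR ~ TLN(1, 1.5) on wide bounds: the dose
        # GSD equals the parameter GSD for a one-factor model
        gsd = 1.5
        grid = AkrGrid()
        grid.add("L0", ACCIDENT_DATE, trunclognorm(1.0, gsd, gsd**-8, gsd**8))
        doses = mission_dose_stochastic(
            [_entry(dt.date(1986, 6, 1))], grid, point(1.0), FAR,
            n=10_000, stream=RngStream(2), subject_id="p1",
        )
        assert 1.45 <= empirical_gsd(doses.values) <= 1.55

    def test_substream_separation_between_subjects(self, unit_grid):
        spec_grid = AkrGrid()
        spec_grid.add("L0", ACCIDENT_DATE, trunclognorm(1.0, 1.4, 0.5, 2.0))
        args = ([_entry(dt.date(1986, 6, 1))], spec_grid, point(0.7), FAR)
        a = mission_dose_stochastic(*args, n=20, stream=RngStream(3), subject_id="p1")
        b = mission_dose_stochastic(*args, n=20, stream=RngStream(3), subject_id="p2")
        assert not np.array_equal(a.values, b.values)

    def test_mean_matches_analytic_product_mean(self):
        # E[dose] = C_g * E[AKR] * E[dt] * E[LF] for independent factors
        gsd = 1.4
        gm = 2.0
        grid = AkrGrid()
        grid.add("L0", ACCIDENT_DATE, trunclognorm(gm, gsd, gm * gsd**-8, gm * gsd**8))
        entry = ItineraryEntry(
            day=dt.date(1986, 6, 1), location_id="L0", activity="w",
            duration=point(3.0), lf=point(0.8),
        )
        doses = mission_dose_stochastic(
            [entry], grid, point(0.710), FAR, n=10_000,
            stream=RngStream(4), subject_id="p",
        )
        analytic = 0.710 * am_from_gm_gsd(gm, gsd) * 3.0 * 0.8
        se = doses.values.std() / 100.0
        assert abs(doses.central() - analytic) < 3 * se

    def test_crn_across_cutoffs(self, unit_grid):
        # identical substreams under different cutoffs: the longer window
        # dominates realization by realization
        grid = AkrGrid()
        grid.add("L0", ACCIDENT_DATE, trunclognorm(1.0, 1.5, 0.2, 5.0))
        entries = [_entry(dt.date(1986, 6, d)) for d in range(1, 10)]
        short = mission_dose_stochastic(
            entries, grid, point(0.7), dt.date(1986, 6, 4),
            n=200, stream=RngStream(5), subject_id="p",
        )
        long = mission_dose_stochastic(
            entries, grid, point(0.7), dt.date(1986, 6, 9),
            n=200, stream=RngStream(5), subject_id="p",
        )
        assert np.all(long.values >= short.values - 1e-12)


class TestPripyat:
    def _entry(self, start, end, akr=1.0, lf=1.0):
        return PripyatEntry(
            start_hour=start, end_hour=end, location_kind="outdoor",
            akr=point(akr), lf=point(lf),
        )

    def test_single_term_product(self):
        doses = pripyat_dose(
            [self._entry(0, 10, akr=0.5)], point(0.586), n=10,
            stream=RngStream(1), subject_id="m",
        )
        np.testing.assert_allclose(doses.values, 0.586 * 0.5 * 10)

    def test_additivity_across_locations(self):
        both = pripyat_dose_deterministic(
            [self._entry(0, 5, akr=1.0), self._entry(5, 12, akr=0.3)], 0.586
        )
        single = pripyat_dose_deterministic(
            [self._entry(0, 5, akr=1.0)], 0.586
        ) + pripyat_dose_deterministic([self._entry(5, 12, akr=0.3)], 0.586)
        assert both == pytest.approx(single)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pripyat_dose([self._entry(0, 5), self._entry(4, 8)], point(0.586), n=5)

    def test_indoor_lf_realizations_within_tln_bounds(self):
        gm = 0.049
        entry = PripyatEntry(
            start_hour=0, end_hour=10, location_kind="apartment",
            akr=point(1.0), lf=trunclognorm(gm, 1.3, 0.6 * gm, 1.7 * gm),
            building_id="B", floor=1,
        )
        doses = pripyat_dose(
            [entry], point(1.0), n=2000, stream=RngStream(2), subject_id="m"
        )
        factors = doses.values / 10.0
        assert factors.min() >= 0.6 * gm - 1e-12
        assert factors.max() <= 1.7 * gm + 1e-12

    def test_cutoff_hour_clips_exposure(self):
        full = pripyat_dose_deterministic([self._entry(0, 10)], 1.0)
        clipped = pripyat_dose_deterministic([self._entry(0, 10)], 1.0, cutoff_hour=4)
        assert clipped == pytest.approx(0.4 * full)
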