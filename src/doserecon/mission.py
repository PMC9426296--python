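"""Time-and-motion external dosimetry for the cleanup mission and Pripyat.

External dose is the product sum ``C_g * sum_i AKR(t_i) * dt_i * LF_i`` over
itinerary entries: air kerma rate at the place and time of an activity,
the activity's duration, and a location factor encoding building and
environment shielding.  ``C_g`` converts air kerma rate to gonadal
absorbed dose rate (isotropic geometry, 0.3 MeV photons): 0.710 for
testes, 0.586 for ovaries.

All parameters of this pathway carry unshared (subject-dependent) errors;
the stochastic kernels redraw every parameter independently per
realization, except ``C_g``, which is a property of the person's anatomy
and is drawn once per realization, not per entry.
"""

from __future__ import annotations

import datetime as _dt
from bisect import bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import Pathway, Sex, StochasticDoses, WindowKind
from .distributions import DistributionSpec, RngStream, truncnorm

#: Central air-kerma-to-gonadal-dose conversion coefficients (unitless).
CG_CENTRAL = {Sex.MALE: 0.710, Sex.FEMALE: 0.586}


def cg_spec(sex: Sex) -> DistributionSpec:
    """TN(AM, 0.1*AM, AM-2SD, AM+2SD) spec for the conversion coefficient."""
    am = CG_CENTRAL[sex]
    sd = 0.1 * am
    return truncnorm(am, sd, am - 2 * sd, am + 2 * sd)


def duration_spec(am_hours: float, cv: Optional[float] = None) -> DistributionSpec:
    """Uniform duration spec U((1-CV)AM, (1+CV)AM), defaulting to CV = 0.1."""
    from .distributions import uniform

    if am_hours < 0:
        raise ValueError("duration must be nonnegative")
    c = 0.1 if cv is None else cv
    return uniform((1 - c) * am_hours, (1 + c) * am_hours)


def lf_spec_site(am: float) -> DistributionSpec:
    """Location-factor spec for cleanup-site activities: TN(AM, 0.25 AM, +-2SD)."""
    sd = 0.25 * am
    return truncnorm(am, sd, max(am - 2 * sd, 0.0), am + 2 * sd)


def lf_spec_pripyat(gm: float) -> DistributionSpec:
    """Location-factor spec for Pripyat locations: TLN(GM, 1.3, 0.6 GM, 1.7 GM)."""
    from .distributions import trunclognorm

    return trunclognorm(gm, 1.3, 0.6 * gm, 1.7 * gm)


def daily_average_lf(day_lf: float, night_lf: float, sleep_hours: float = 8.0) -> float:
    """Occupancy-weighted daily indoor location factor.

    Weights the daytime LF by the waking hours and the sleeping-area LF by
    *sleep_hours* (default 8 h sleeping).
    """
    if not 0 <= sleep_hours <= 24:
        raise ValueError("sleep hours must lie in [0, 24]")
    if day_lf < 0 or night_lf < 0:
        raise ValueError("location factors must be nonnegative")
    return ((24.0 - sleep_hours) * day_lf + sleep_hours * night_lf) / 24.0


@dataclass(frozen=True)
class ItineraryEntry:
    """One cleanup activity: a day, a place, a duration and a shielding factor."""

    day: _dt.date
    location_id: str
    activity: str
    duration: DistributionSpec  # hours
    lf: DistributionSpec  # unitless

    def __post_init__(self) -> None:
        if self.duration.central() < 0:
            raise ValueError("duration central value must be nonnegative")


class AkrGrid:
    """Air-kerma-rate field: (location, date) -> TLN spec in mGy/h.

    Lookups between tabulated dates are piecewise-constant: the cell with
    the latest date on or before the query date applies.
    """

    def __init__(self) -> None:
        self._cells: dict[str, list[tuple[_dt.date, DistributionSpec]]] = {}
        self._sorted = True

    def add(self, location_id: str, date: _dt.date, spec: DistributionSpec) -> None:
        self._cells.setdefault(location_id, []).append((date, spec))
        self._sorted = False

    def _ensure_sorted(self) -> None:
        if not self._sorted:
            for cells in self._cells.values():
                cells.sort(key=lambda c: c[0])
            self._sorted = True

    def locations(self) -> list[str]:
        return sorted(self._cells)

    def lookup_cell(self, location_id: str, date: _dt.date) -> tuple[_dt.date, DistributionSpec]:
        """The governing grid cell (its date and spec) for a query date."""
        self._ensure_sorted()
        cells = self._cells.get(location_id)
        if not cells:
            raise KeyError(f"no air-kerma-rate data for location {location_id!r}")
        dates = [c[0] for c in cells]
        i = bisect_right(dates, date) - 1
        if i < 0:
            raise KeyError(
                f"no air-kerma-rate data for location {location_id!r} on or before {date}"
            )
        return cells[i]

    def lookup(self, location_id: str, date: _dt.date) -> DistributionSpec:
        return self.lookup_cell(location_id, date)[1]

    def items(self):
        self._ensure_sorted()
        for loc in sorted(self._cells):
            for date, spec in self._cells[loc]:
                yield loc, date, spec


@dataclass(frozen=True)
class PripyatEntry:
    """One interval of the hour-by-hour occupancy timeline.

    Hours count from the accident origin (01:23 on the accident date is
    collapsed to hour zero).  ``location_kind`` distinguishes the apartment
    (building, floor), outdoor locations, and other indoor places.
    """

    start_hour: float
    end_hour: float
    location_kind: str  # "apartment" | "outdoor" | "other_indoor"
    akr: DistributionSpec  # mGy/h
    lf: DistributionSpec
    building_id: Optional[str] = None
    floor: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end_hour <= self.start_hour:
            raise ValueError("timeline entry must have positive duration")

    @property
    def duration_hours(self) -> float:
        return self.end_hour - self.start_hour


def _entries_before(
    itinerary: Sequence[ItineraryEntry], cutoff: _dt.date
) -> list[ItineraryEntry]:
    # window-end exclusive: exposure on the cutoff date is not counted
    return [e for e in itinerary if e.day < cutoff]


def mission_dose_deterministic(
    itinerary: Sequence[ItineraryEntry],
    akr_grid: AkrGrid,
    c_g: float,
    cutoff: _dt.date,
) -> float:
    """Deterministic mission dose (mGy) at central parameter values."""
    total = 0.0
    for e in _entries_before(itinerary, cutoff):
        try:
            akr = akr_grid.lookup(e.location_id, e.day)
        except KeyError as err:
            raise KeyError(
                f"itinerary entry ({e.day}, {e.location_id!r}, {e.activity!r}): {err}"
            ) from err
        total += akr.central() * e.duration.central() * e.lf.central()
    return c_g * total


def mission_dose_stochastic(
    itinerary: Sequence[ItineraryEntry],
    akr_grid: AkrGrid,
    c_g_spec: DistributionSpec,
    cutoff: _dt.date,
    n: int = 10_000,
    stream: RngStream | None = None,
    subject_id: str = "",
    window_kind: WindowKind = WindowKind.DOB38,
) -> StochasticDoses:
    """n stochastic mission dose realizations; all parameters unshared.

    Every itinerary entry redraws its air kerma rate, duration and location
    factor independently per realization; the anatomical conversion
    coefficient is drawn once per realization.
    """
    stream = stream or RngStream(0)
    cg = c_g_spec.sample(stream.stream(subject_id, "cg"), n)
    total = np.zeros(n)
    # substreams are keyed by the entry's position in the full itinerary
    # (or by the AKR grid cell), so the same draws recur under any cutoff:
    # common random numbers across the DOB-51 and DOB-38 windows.  The air
    # kerma rate is one interpolated-field value per grid cell, so entries
    # resolving the same cell share its realization.
    akr_cache: dict[tuple, np.ndarray] = {}
    for idx, e in enumerate(itinerary):
        if e.day >= cutoff:
            continue
        try:
            cell_date, akr_spec = akr_grid.lookup_cell(e.location_id, e.day)
        except KeyError as err:
            raise KeyError(
                f"itinerary entry ({e.day}, {e.location_id!r}, {e.activity!r}): {err}"
            ) from err
        cell = (e.location_id, cell_date)
        if cell not in akr_cache:
            akr_cache[cell] = akr_spec.sample(
                stream.stream(subject_id, "akr", e.location_id, cell_date.isoformat()),
                n,
            )
        akr = akr_cache[cell]
        dt = e.duration.sample(stream.stream(subject_id, "dt", idx), n)
        lf = e.lf.sample(stream.stream(subject_id, "lf", idx), n)
        total += akr * dt * lf
    return StochasticDoses(
        subject_id=subject_id,
        pathway=Pathway.MISSION,
        window_kind=window_kind,
        values=cg * total,
        seed=stream.seed,
    )


def _check_timeline(occupancy: Sequence[PripyatEntry]) -> None:
    ordered = sorted(occupancy, key=lambda e: e.start_hour)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_hour < a.end_hour - 1e-9:
            raise ValueError(
                f"overlapping timeline entries at hours {b.start_hour}-{a.end_hour}"
            )


def pripyat_dose(
    occupancy: Sequence[PripyatEntry],
    c_g_spec: DistributionSpec,
    n: int = 10_000,
    stream: RngStream | None = None,
    subject_id: str = "",
    window_kind: WindowKind = WindowKind.DOB38,
    cutoff_hour: Optional[float] = None,
) -> StochasticDoses:
    """n stochastic dose realizations for a Pripyat occupancy timeline.

    Same kernel as the mission dose: each timeline interval contributes
    AKR * duration * LF; entries are clipped at ``cutoff_hour`` when the
    exposure window closes before the departure from the zone.
    """
    _check_timeline(occupancy)
    stream = stream or RngStream(0)
    cg = c_g_spec.sample(stream.stream(subject_id, "cg"), n)
    total = np.zeros(n)
    for idx, e in enumerate(occupancy):
        hours = e.duration_hours
        if cutoff_hour is not None:
            hours = min(e.end_hour, cutoff_hour) - e.start_hour
            if hours <= 0:
                continue
        akr = e.akr.sample(stream.stream(subject_id, "pakr", idx), n)
        lf = e.lf.sample(stream.stream(subject_id, "plf", idx), n)
        total += akr * hours * lf
    return StochasticDoses(
        subject_id=subject_id,
        pathway=Pathway.PRIPYAT,
        window_kind=window_kind,
        values=cg * total,
        seed=stream.seed,
    )


def pripyat_dose_deterministic(
    occupancy: Sequence[PripyatEntry],
    c_g: float,
    cutoff_hour: Optional[float] = None,
) -> float:
    """Deterministic Pripyat dose (mGy) at central parameter values."""
    _check_timeline(occupancy)
    total = 0.0
    for e in occupancy:
        hours = e.duration_hours
        if cutoff_hour is not None:
            hours = min(e.end_hour, cutoff_hour) - e.start_hour
            if hours <= 0:
                continue
        total += e.akr.central() * hours * e.lf.central()
    return c_g * total
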