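"""Domain types and calendar logic for preconception dose windows.

All exposure integration runs on whole calendar days from the accident
origin (1986-04-26).  Two windows are defined per child: one ending 51
weeks before the child's date of birth (the spermatogonial stem-cell
window) and one ending 38 weeks before birth (the preconception window,
additionally covering the ~3-month spermatid stage).  Window ends are
exclusive: exposure on the end date itself is not counted, which makes
the DOB-51 -> DOB-38 difference exactly 91 days for every child.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

#: Day-zero of all exposure integrations (the accident date).
ACCIDENT_DATE = _dt.date(1986, 4, 26)

#: Legal end of cleanup activities; mission doses never accrue past this date.
MISSION_LEGAL_END = _dt.date(1990, 12, 31)

#: Children are eligible if born at least 46 weeks after the accident.
ELIGIBILITY_DAYS = 46 * 7


class WindowKind(str, Enum):
    DOB51 = "DOB51"
    DOB38 = "DOB38"

    @property
    def weeks(self) -> int:
        return 51 if self is WindowKind.DOB51 else 38


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"

    @property
    def gonad(self) -> str:
        return "testes" if self is Sex.MALE else "ovaries"


class Pathway(str, Enum):
    MISSION = "mission"
    PRIPYAT = "pripyat"
    RESIDENTIAL_EXTERNAL = "residential_external"
    RESIDENTIAL_INGESTION = "residential_ingestion"


#: Exposure categories used for trio ascertainment (never in dose math).
EXPOSURE_CATEGORIES = ("A", "B", "C", "D", "E")

#: Dose-interval bins (mGy), left-closed, matching the reporting tables.
DOSE_BIN_EDGES = (0.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)
DOSE_BIN_LABELS = (
    "<3", "3.0-9.99", "10-29.9", "30-99.9", "100-299.9", "300-999.9", "1000+",
)


def days_since_accident(d: _dt.date) -> int:
    """Whole days from the accident date to *d* (negative if before)."""
    return (d - ACCIDENT_DATE).days


def window_end(dob: _dt.date, weeks: int) -> _dt.date:
    """Date *weeks* weeks before a date of birth.

    Raises ``ValueError`` if the DOB precedes the accident date.  The
    returned date may itself precede the accident, in which case the
    effective integration window is empty and all doses are zero.
    """
    if dob < ACCIDENT_DATE:
        raise ValueError(f"date of birth {dob} precedes the accident date")
    return dob - _dt.timedelta(days=7 * weeks)


def mission_cutoff(win_end: _dt.date, mission_end: _dt.date) -> _dt.date:
    """Earliest of the window end, the mission end and the legal cutoff."""
    return min(win_end, mission_end, MISSION_LEGAL_END)


def is_eligible(dob: _dt.date) -> bool:
    """True iff the child was born 46 weeks or later after the accident."""
    return dob >= ACCIDENT_DATE + _dt.timedelta(days=ELIGIBILITY_DAYS)


def dose_category(dose: float) -> str:
    """Dose-interval label for a nonnegative dose in mGy.

    Bins are left-closed: [0,3), [3,10), [10,30), [30,100), [100,300),
    [300,1000), [1000,inf).
    """
    if dose < 0:
        raise ValueError(f"dose must be nonnegative, got {dose}")
    for hi, label in zip(DOSE_BIN_EDGES[1:], DOSE_BIN_LABELS[:-1]):
        if dose < hi:
            return label
    return DOSE_BIN_LABELS[-1]


def dose_bin_index(dose: float) -> int:
    """Index of the dose-interval bin containing *dose* (0-based)."""
    return DOSE_BIN_LABELS.index(dose_category(dose))


@dataclass(frozen=True)
class ExposureWindow:
    """Integration window [accident date, DOB - 51w or 38w), end exclusive."""

    end: _dt.date
    kind: WindowKind
    start: _dt.date = ACCIDENT_DATE

    @classmethod
    def for_child(cls, dob: _dt.date, kind: WindowKind) -> "ExposureWindow":
        return cls(end=window_end(dob, kind.weeks), kind=kind)

    @property
    def length_days(self) -> int:
        """Window length in days, clipped to zero if the end precedes the start."""
        return max(0, (self.end - self.start).days)

    @property
    def is_empty(self) -> bool:
        return self.end <= self.start

    def clip_interval(self, t1: _dt.date, t2: _dt.date) -> tuple[int, int]:
        """Intersect [t1, t2) with the window, in days since the accident.

        Returns ``(a, b)`` with ``a >= 0``; an empty intersection gives
        ``a == b``.
        """
        a = max(days_since_accident(t1), days_since_accident(self.start))
        b = min(days_since_accident(t2), days_since_accident(self.end))
        a = max(a, 0)
        b = max(b, a)
        return a, b


@dataclass(frozen=True)
class Child:
    id: str
    trio_id: str
    dob: _dt.date

    def __post_init__(self) -> None:
        if self.dob < ACCIDENT_DATE:
            raise ValueError(f"child {self.id}: DOB precedes the accident")

    @property
    def eligible(self) -> bool:
        return is_eligible(self.dob)

    def window(self, kind: WindowKind) -> ExposureWindow:
        return ExposureWindow.for_child(self.dob, kind)


@dataclass
class Parent:
    """A study parent with whatever exposure pathways apply (possibly none)."""

    id: str
    sex: Sex
    pathways: frozenset[Pathway] = field(default_factory=frozenset)
    itinerary_ref: Optional[str] = None
    residence_ref: Optional[str] = None

    @property
    def gonad(self) -> str:
        return self.sex.gonad

    def has(self, pathway: Pathway) -> bool:
        return pathway in self.pathways


@dataclass(frozen=True)
class Trio:
    id: str
    category: str
    father_id: str
    mother_id: str
    child_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in EXPOSURE_CATEGORIES:
            raise ValueError(f"unknown exposure category {self.category!r}")


@dataclass
class StochasticDoses:
    """Matrix row of dose realizations for one subject x pathway x window.

    ``values`` holds n nonnegative realizations (mGy).  An empty vector
    flags a structurally absent pathway (``structural_zero``).
    """

    subject_id: str
    pathway: Pathway
    window_kind: WindowKind
    values: np.ndarray
    seed: Optional[int] = None
    structural_zero: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and self.values.min() < -1e-12:
            raise ValueError("dose realizations must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def central(self) -> float:
        """Arithmetic mean of the realizations (the central dose estimate)."""
        if self.values.size == 0:
            raise ValueError("no realizations")
        return float(self.values.mean())

    def gsd(self) -> float:
        """Geometric standard deviation of the (positive) realizations."""
        v = self.values
        if v.size < 2 or np.any(v <= 0):
            raise ValueError("GSD requires >= 2 strictly positive realizations")
        return float(np.exp(np.std(np.log(v), ddof=0)))


@dataclass
class PathwayDose:
    """Central estimate (arithmetic mean of realizations) for one pathway."""

    subject_id: str
    pathway: Pathway
    window_kind: WindowKind
    central_mgy: float
    realizations: Optional["object"] = None  # StochasticDoses, kept loose

    def __post_init__(self) -> None:
        if self.central_mgy < 0:
            raise ValueError("central estimate must be nonnegative")


def total_dose(pathway_doses: Sequence[PathwayDose]) -> float:
    """Sum of pathway central estimates; duplicate pathways are an error."""
    seen = set()
    total = 0.0
    for pd in pathway_doses:
        key = (pd.pathway, pd.window_kind)
        if key in seen:
            raise ValueError(f"duplicate pathway dose for {key}")
        seen.add(key)
        total += pd.central_mgy
    return total
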