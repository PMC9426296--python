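"""Synthetic cohort generator.

Emulates the input side of the pipeline — questionnaire-derived mission
itineraries, Pripyat occupancy timelines, residence histories over
contaminated settlements and foodstuff-consumption diaries — with the
statistical structure the analysis assumes, so every stage runs without
any confidential study data.

Five ascertainment categories drive who gets which exposure records:

* A: exposed father (cleanup itinerary), unexposed mother;
* B: exposed mother (itinerary or Pripyat timeline), unexposed father;
* C: both exposed;
* D: both unexposed (residence in low-deposition settlements only);
* E: father a highly exposed early responder (early, high-rate itinerary).

Dose-scale targets (e.g. a father cleanup-pathway median near 144 mGy)
are reached by calibrating air-kerma-rate magnitudes and itinerary
lengths analytically — never by back-solving doses — which keeps the
generator an honest input-side emulator.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    ACCIDENT_DATE,
    Child,
    Parent,
    Pathway,
    Sex,
    Trio,
)
from .distributions import RngStream, trunclognorm
from .ingestion import DietRecord
from .mission import (
    AkrGrid,
    ItineraryEntry,
    PripyatEntry,
    daily_average_lf,
    duration_spec,
    lf_spec_pripyat,
    lf_spec_site,
)
from .resexternal import HOUSE_TYPES, ResidenceRecord, SettlementRecord

#: Printed day/night location factors by floor for the reference
#: five-storey Pripyat apartment building (daily average assumes 8 h sleep).
PRIPYAT_FLOOR_LF = {1: (0.072, 0.0018), 3: (0.047, 0.0012), 5: (0.038, 0.0001)}


@dataclass
class CohortConfig:
    """Study-condition knobs of the generator (defaults match the design)."""

    n_trios: Mapping[str, int] = field(
        default_factory=lambda: {"A": 71, "B": 51, "C": 59, "D": 51, "E": 66}
    )
    children_weights: tuple[float, float, float] = (242.0, 52.0, 4.0)
    dob_start: _dt.date = _dt.date(1987, 3, 14)
    dob_end: _dt.date = _dt.date(2005, 7, 15)
    early_dob_fraction: float = 0.4  # born by end of 1990

    # analytic dose-scale calibration (see module docstring)
    father_mission_akr_median: float = 2.0  # mGy/h at the accident date
    mother_mission_akr_median: float = 0.38
    e_category_akr_scale: float = 2.0
    mission_days_median: dict[str, float] = field(
        default_factory=lambda: {"father": 30.0, "mother": 10.0}
    )
    mission_days_gsd: float = 2.2
    mission_hours_per_day: float = 6.0
    site_lf_am: float = 0.8
    akr_decay_half_days: float = 180.0
    akr_gsd_range: tuple[float, float] = (1.3, 2.2)

    pripyat_outdoor_akr: float = 0.9  # mGy/h shortly after the accident
    pripyat_outdoor_fraction: float = 0.3

    n_settlements: int = 40
    deposition_median: float = 30.0  # kBq/m2
    deposition_gsd: float = 4.0
    multi_residence_prob: float = 0.23
    mushroom_prob: float = 0.5

    #: include the two documented extreme scenarios as extra fixture trios
    include_extreme_trios: bool = False


@dataclass
class CohortBundle:
    """Complete in-memory input set for a pipeline run."""

    trios: list[Trio]
    children: list[Child]
    parents: dict[str, Parent]
    itineraries: dict[str, list[ItineraryEntry]]
    akr_grid: AkrGrid
    pripyat_timelines: dict[str, list[PripyatEntry]]
    residences: dict[str, list[ResidenceRecord]]
    settlements: dict[str, SettlementRecord]
    diets: dict[str, DietRecord]
    seed: int = 0


def _lognormal(rng: np.random.Generator, median: float, gsd: float) -> float:
    return float(median * math.exp(math.log(gsd) * rng.standard_normal()))


def generate_akr_grid(
    locations: Sequence[str],
    dates: Sequence[_dt.date],
    base_rates: Mapping[str, float],
    seed: int = 0,
    decay_half_days: float = 180.0,
    gsd_range: tuple[float, float] = (1.3, 2.2),
) -> AkrGrid:
    """Air-kerma-rate grid with fallout-like decline in time.

    Each (location, date) cell gets a truncated-lognormal spec whose GM is
    the location's accident-date rate decayed with *decay_half_days* and
    whose GSD is drawn uniformly in *gsd_range* (within the [1.2, 3.0]
    band typical of interpolated exposure-rate fields).
    """
    if not locations or not dates:
        raise ValueError("need at least one location and one date")
    stream = RngStream(seed)
    grid = AkrGrid()
    lam = math.log(2.0) / decay_half_days
    for loc in locations:
        rng = stream.stream("akr", loc)
        for date in sorted(dates):
            t = max(0, (date - ACCIDENT_DATE).days)
            gm = base_rates[loc] * math.exp(-lam * t)
            gsd = float(rng.uniform(*gsd_range))
            grid.add(loc, date, trunclognorm(gm, gsd, gm / gsd**2, gm * gsd**2))
    return grid


def generate_residence_history(
    parent_id: str,
    settlements: Mapping[str, SettlementRecord],
    seed: int,
    start: _dt.date,
    end: _dt.date,
    multi_prob: float = 0.23,
    pool: Optional[Sequence[str]] = None,
) -> list[ResidenceRecord]:
    """Non-overlapping, gap-free residence intervals covering [start, end)."""
    rng = RngStream(seed).stream("residence", parent_id)
    ids = list(pool if pool is not None else sorted(settlements))
    n_places = 2 if (len(ids) > 1 and rng.random() < multi_prob) else 1
    chosen = [ids[int(rng.integers(len(ids)))] for _ in range(n_places)]
    if n_places == 2 and chosen[1] == chosen[0]:
        chosen[1] = ids[(ids.index(chosen[0]) + 1) % len(ids)]
    total_days = (end - start).days
    if n_places == 1:
        cuts = [0, total_days]
    else:
        split = int(rng.integers(30, max(31, total_days - 30)))
        cuts = [0, split, total_days]
    records = []
    for i, sid in enumerate(chosen):
        records.append(
            ResidenceRecord(
                parent_id=parent_id,
                settlement_id=sid,
                start=start + _dt.timedelta(days=cuts[i]),
                end=start + _dt.timedelta(days=cuts[i + 1]),
                house_type=HOUSE_TYPES[int(rng.integers(len(HOUSE_TYPES)))],
                zone="other",
            )
        )
    return records


def _generate_settlements(config: CohortConfig, stream: RngStream) -> dict[str, SettlementRecord]:
    rng = stream.stream("settlements")
    out = {}
    countries = ["Ukraine"] * 7 + ["Belarus", "Russia", "Ukraine"]
    for i in range(config.n_settlements):
        sigma = _lognormal(rng, config.deposition_median, config.deposition_gsd)
        sigma = float(np.clip(sigma, 1.4, 18_530.0))
        out[f"S{i:03d}"] = SettlementRecord(
            id=f"S{i:03d}",
            country=countries[i % len(countries)],
            cs137_kbq_m2=round(sigma, 2),
            area_id=f"area{i % 5}",
        )
    return out


def _sample_dob(config: CohortConfig, rng: np.random.Generator) -> _dt.date:
    early_end = _dt.date(1990, 12, 31)
    if rng.random() < config.early_dob_fraction:
        span = (early_end - config.dob_start).days
    else:
        span = (config.dob_end - config.dob_start).days
    return config.dob_start + _dt.timedelta(days=int(rng.integers(0, span + 1)))


def _generate_itinerary(
    parent_id: str,
    role: str,
    category: str,
    config: CohortConfig,
    stream: RngStream,
    locations: Sequence[str],
) -> list[ItineraryEntry]:
    rng = stream.stream("itinerary", parent_id)
    n_days = int(
        np.clip(
            _lognormal(rng, config.mission_days_median[role], config.mission_days_gsd),
            3,
            120,
        )
    )
    if category == "E":
        start_day = int(rng.integers(0, 10))
    else:
        start_day = int(rng.integers(5, 400))
    entries = []
    for d in range(n_days):
        day = ACCIDENT_DATE + _dt.timedelta(days=start_day + d)
        loc = locations[int(rng.integers(len(locations)))]
        hours = float(np.clip(rng.normal(config.mission_hours_per_day, 1.5), 1.0, 12.0))
        lf_am = float(np.clip(rng.normal(config.site_lf_am, 0.15), 0.2, 1.2))
        entries.append(
            ItineraryEntry(
                day=day,
                location_id=loc,
                activity="cleanup",
                duration=duration_spec(round(hours, 2), cv=0.1),
                lf=lf_spec_site(round(lf_am, 3)),
            )
        )
    return entries


def _generate_pripyat_timeline(
    parent_id: str, config: CohortConfig, stream: RngStream
) -> list[PripyatEntry]:
    rng = stream.stream("pripyat", parent_id)
    depart = float(rng.uniform(30.0, 110.0))  # hours to departure from the zone
    floor = (1, 3, 5)[int(rng.integers(3))]
    day_lf, night_lf = PRIPYAT_FLOOR_LF[floor]
    indoor_gm = daily_average_lf(day_lf, night_lf, 8.0)
    outdoor_gm = 0.85
    lam = math.log(2.0) / 72.0  # cloud+deposit field declines over ~3 days
    entries: list[PripyatEntry] = []
    t = 0.0
    outdoor_next = False
    while t < depart:
        frac = config.pripyat_outdoor_fraction
        block = float(rng.uniform(2.0, 8.0))
        end = min(t + block, depart)
        outdoor = outdoor_next if rng.random() < 0.8 else not outdoor_next
        gm_lf = outdoor_gm if outdoor else indoor_gm
        akr_gm = config.pripyat_outdoor_akr * math.exp(-lam * t)
        entries.append(
            PripyatEntry(
                start_hour=t,
                end_hour=end,
                location_kind="outdoor" if outdoor else "apartment",
                akr=trunclognorm(akr_gm, 1.5, akr_gm / 1.5**2, akr_gm * 1.5**2),
                lf=lf_spec_pripyat(gm_lf),
                building_id=None if outdoor else "B01",
                floor=None if outdoor else floor,
            )
        )
        outdoor_next = rng.random() < frac
        t = end
    return entries


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortBundle:
    """Generate a complete, schema-valid synthetic cohort bundle.

    Deterministic under *seed*: the same seed reproduces the identical
    bundle (and byte-identical files once written).
    """
    config = config or CohortConfig()
    stream = RngStream(seed)
    settlements = _generate_settlements(config, stream)
    low_ids = sorted(
        sid for sid, s in settlements.items() if s.cs137_kbq_m2 < 37.0
    ) or sorted(settlements)
    site_locs = [f"L{i:02d}" for i in range(12)]
    mother_locs = [f"M{i:02d}" for i in range(6)]
    grid_rng = stream.stream("akr_levels")
    base_rates = {}
    for loc in site_locs:
        base_rates[loc] = _lognormal(grid_rng, config.father_mission_akr_median, 1.8)
    for loc in mother_locs:
        base_rates[loc] = _lognormal(grid_rng, config.mother_mission_akr_median, 1.8)
    e_locs = [f"E{i:02d}" for i in range(4)]
    for loc in e_locs:
        base_rates[loc] = _lognormal(
            grid_rng, config.father_mission_akr_median * config.e_category_akr_scale, 1.8
        )
    grid_dates = [
        ACCIDENT_DATE + _dt.timedelta(days=d) for d in range(0, 1700, 30)
    ]
    akr_grid = generate_akr_grid(
        site_locs + mother_locs + e_locs,
        grid_dates,
        base_rates,
        seed=seed,
        decay_half_days=config.akr_decay_half_days,
        gsd_range=config.akr_gsd_range,
    )

    trios: list[Trio] = []
    children: list[Child] = []
    parents: dict[str, Parent] = {}
    itineraries: dict[str, list[ItineraryEntry]] = {}
    pripyat: dict[str, list[PripyatEntry]] = {}
    residences: dict[str, list[ResidenceRecord]] = {}
    diets: dict[str, DietRecord] = {}

    w = np.asarray(config.children_weights, dtype=float)
    w = w / w.sum()
    t_idx = 0
    for category in sorted(config.n_trios):
        for _ in range(config.n_trios[category]):
            t_idx += 1
            tid = f"T{t_idx:04d}"
            rng = stream.stream("trio", tid)
            n_children = 1 + int(rng.choice(3, p=w))
            kids = []
            for c in range(n_children):
                dob = _sample_dob(config, rng)
                cid = f"{tid}C{c+1}"
                children.append(Child(id=cid, trio_id=tid, dob=dob))
                kids.append(cid)
            fid, mid = f"{tid}F", f"{tid}M"
            last_dob = max(ch.dob for ch in children if ch.trio_id == tid)
            res_end = last_dob

            father_paths: set[Pathway] = {Pathway.RESIDENTIAL_EXTERNAL,
                                          Pathway.RESIDENTIAL_INGESTION}
            mother_paths = set(father_paths)
            if category in ("A", "C", "E"):
                father_paths.add(Pathway.MISSION)
                locs = e_locs if category == "E" else site_locs
                itineraries[fid] = _generate_itinerary(
                    fid, "father", category, config, stream, locs
                )
            if category in ("B", "C"):
                if stream.stream("mexp", mid).random() < 0.5:
                    mother_paths.add(Pathway.MISSION)
                    itineraries[mid] = _generate_itinerary(
                        mid, "mother", category, config, stream, mother_locs
                    )
                else:
                    mother_paths.add(Pathway.PRIPYAT)
                    pripyat[mid] = _generate_pripyat_timeline(mid, config, stream)
            if category == "C" and stream.stream("fprip", fid).random() < 0.3:
                father_paths.add(Pathway.PRIPYAT)
                pripyat[fid] = _generate_pripyat_timeline(fid, config, stream)

            pool = low_ids if category == "D" else None
            for pid, sex, paths in (
                (fid, Sex.MALE, father_paths),
                (mid, Sex.FEMALE, mother_paths),
            ):
                parents[pid] = Parent(id=pid, sex=sex, pathways=frozenset(paths))
                residences[pid] = generate_residence_history(
                    pid,
                    settlements,
                    seed,
                    ACCIDENT_DATE,
                    res_end,
                    multi_prob=config.multi_residence_prob,
                    pool=pool,
                )
                drng = stream.stream("diet", pid)
                rates = {
                    "milk": round(float(drng.uniform(0.2, 0.6)), 3),
                    "milk_products": round(float(drng.uniform(0.05, 0.2)), 3),
                    "meat": round(float(drng.uniform(0.05, 0.25)), 3),
                    "potatoes": round(float(drng.uniform(0.2, 0.5)), 3),
                    "root_vegetables": round(float(drng.uniform(0.1, 0.3)), 3),
                }
                if drng.random() < config.mushroom_prob:
                    rates["mushrooms"] = float("nan")  # reported only as "yes"
                diets[pid] = DietRecord(
                    parent_id=pid,
                    rates=rates,
                    sources={"milk": "local" if drng.random() < 0.7 else "shop"},
                )
            trios.append(
                Trio(
                    id=tid,
                    category=category,
                    father_id=fid,
                    mother_id=mid,
                    child_ids=tuple(kids),
                )
            )

    if config.include_extreme_trios:
        _add_extreme_trios(
            config, stream, trios, children, parents, itineraries, pripyat,
            residences, diets, settlements, e_locs,
        )

    return CohortBundle(
        trios=trios,
        children=children,
        parents=parents,
        itineraries=itineraries,
        akr_grid=akr_grid,
        pripyat_timelines=pripyat,
        residences=residences,
        settlements=settlements,
        diets=diets,
        seed=seed,
    )


def _add_extreme_trios(
    config, stream, trios, children, parents, itineraries, pripyat,
    residences, diets, settlements, e_locs,
):
    """Two optional tail-behaviour fixtures: an early-responder father with
    a multi-Gy mission history, and a mother who walked near the plant on
    the accident day during an otherwise ordinary Pripyat residence."""
    tid = "TX001"
    dob = _dt.date(1988, 6, 1)
    children.append(Child(id=f"{tid}C1", trio_id=tid, dob=dob))
    fid, mid = f"{tid}F", f"{tid}M"
    parents[fid] = Parent(id=fid, sex=Sex.MALE,
                          pathways=frozenset({Pathway.MISSION}))
    parents[mid] = Parent(id=mid, sex=Sex.FEMALE,
                          pathways=frozenset({Pathway.PRIPYAT}))
    entries = []
    for d in range(10):
        entries.append(
            ItineraryEntry(
                day=ACCIDENT_DATE + _dt.timedelta(days=d),
                location_id=e_locs[0],
                activity="emergency",
                duration=duration_spec(10.0, cv=0.1),
                lf=lf_spec_site(1.0),
            )
        )
    itineraries[fid] = entries
    akr_gm = 12.0
    pripyat[mid] = [
        PripyatEntry(
            start_hour=6.0, end_hour=6.7, location_kind="outdoor",
            akr=trunclognorm(akr_gm, 1.5, akr_gm / 2.25, akr_gm * 2.25),
            lf=lf_spec_pripyat(1.0),
        )
    ]
    sid = sorted(settlements)[0]
    for pid in (fid, mid):
        residences[pid] = [
            ResidenceRecord(parent_id=pid, settlement_id=sid,
                            start=ACCIDENT_DATE, end=dob)
        ]
        diets[pid] = DietRecord(parent_id=pid, rates={"milk": 0.3})
    trios.append(Trio(id=tid, category="E", father_id=fid, mother_id=mid,
                      child_ids=(f"{tid}C1",)))
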