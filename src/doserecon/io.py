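"""Validated readers/writers for every input schema, the parameter
library, and the end-to-end pipeline orchestrator.

All files are UTF-8 CSVs with a header row and ISO-8601 dates.
``write_bundle`` / ``read_bundle`` round-trip a
:class:`~doserecon.synthetic.CohortBundle` exactly; ``validate_bundle``
reports schema, referential-integrity and date-ordering problems per
file and row; ``run_pipeline`` computes the per-child, per-parent,
per-pathway, per-window dose table with central estimates and GSDs, the
summary tables and a reproducibility manifest.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    Child,
    Parent,
    Pathway,
    Sex,
    StochasticDoses,
    Trio,
    WindowKind,
    is_eligible,
    mission_cutoff,
)
from .distributions import am_from_gm_gsd, gm_from_am_gsd, trunclognorm
from .ingestion import DEFAULT_DF, FOODS, DietRecord, IntakeParams, cf_spec
from .mc import ResidentialSubject, run_2d_mc, run_unshared_mc
from .mission import (
    AkrGrid,
    ItineraryEntry,
    PripyatEntry,
    cg_spec,
    duration_spec,
    lf_spec_pripyat,
    lf_spec_site,
)
from .resexternal import (
    AttenuationParams,
    HOUSE_TYPES,
    ResidenceRecord,
    SettlementRecord,
    behaviour_factor_spec,
    deposition_spec,
    iv_spec,
)
from .summary import (
    crosstab_windows,
    dose_birthyear_correlation,
    gsd_table,
    pathway_summary,
)
from .synthetic import CohortBundle

logger = logging.getLogger(__name__)

BUNDLE_FILES = (
    "cohort.csv",
    "parents.csv",
    "itinerary.csv",
    "akr_grid.csv",
    "pripyat.csv",
    "residence.csv",
    "settlements.csv",
    "diet.csv",
)

_PATHWAY_FLAGS = {
    Pathway.MISSION: "mission",
    Pathway.PRIPYAT: "pripyat",
    Pathway.RESIDENTIAL_EXTERNAL: "residential_external",
    Pathway.RESIDENTIAL_INGESTION: "residential_ingestion",
}


# ---------------------------------------------------------------------------
# writers


def write_bundle(bundle: CohortBundle, out_dir) -> dict:
    """Write every bundle schema plus a checksum manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    trio_by_id = {t.id: t for t in bundle.trios}
    for ch in sorted(bundle.children, key=lambda c: c.id):
        t = trio_by_id[ch.trio_id]
        rows.append(
            dict(
                child_id=ch.id,
                trio_id=ch.trio_id,
                category=t.category,
                dob=ch.dob.isoformat(),
                father_id=t.father_id,
                mother_id=t.mother_id,
            )
        )
    pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)

    rows = []
    for pid in sorted(bundle.parents):
        p = bundle.parents[pid]
        row = dict(parent_id=pid, sex=p.sex.value)
        for pw, flag in _PATHWAY_FLAGS.items():
            row[flag] = int(pw in p.pathways)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "parents.csv", index=False)

    rows = []
    for pid in sorted(bundle.itineraries):
        for e in bundle.itineraries[pid]:
            am = e.duration.central()
            cv = (e.duration.params["max"] - e.duration.params["min"]) / (2 * am) if am else 0.0
            rows.append(
                dict(
                    parent_id=pid,
                    day=e.day.isoformat(),
                    location_id=e.location_id,
                    activity=e.activity,
                    # rounded so write -> read -> write is byte-stable
                    duration_am_h=round(am, 9),
                    duration_cv=round(cv, 6),
                    lf_am=e.lf.params["am"],
                    lf_dist="TN",
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "parent_id", "day", "location_id", "activity",
            "duration_am_h", "duration_cv", "lf_am", "lf_dist",
        ],
    ).to_csv(out / "itinerary.csv", index=False)

    rows = []
    for loc, date, spec in bundle.akr_grid.items():
        gm, gsd = spec.params["gm"], spec.params["gsd"]
        rows.append(
            dict(
                location_id=loc,
                date=date.isoformat(),
                akr_am_mGy_h=round(am_from_gm_gsd(gm, gsd), 12),
                akr_gsd=gsd,
            )
        )
    pd.DataFrame(
        rows, columns=["location_id", "date", "akr_am_mGy_h", "akr_gsd"]
    ).to_csv(out / "akr_grid.csv", index=False)

    rows = []
    for pid in sorted(bundle.pripyat_timelines):
        for e in bundle.pripyat_timelines[pid]:
            rows.append(
                dict(
                    parent_id=pid,
                    start_hour=e.start_hour,
                    end_hour=e.end_hour,
                    location_kind=e.location_kind,
                    building_id=e.building_id or "",
                    floor="" if e.floor is None else e.floor,
                    akr_gm=e.akr.params["gm"],
                    akr_gsd=e.akr.params["gsd"],
                    lf_gm=e.lf.params["gm"],
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "parent_id", "start_hour", "end_hour", "location_kind",
            "building_id", "floor", "akr_gm", "akr_gsd", "lf_gm",
        ],
    ).to_csv(out / "pripyat.csv", index=False)

    rows = []
    for pid in sorted(bundle.residences):
        for r in bundle.residences[pid]:
            rows.append(
                dict(
                    parent_id=pid,
                    settlement_id=r.settlement_id,
                    start_date=r.start.isoformat(),
                    end_date=r.end.isoformat(),
                    house_type=r.house_type,
                    zone=r.zone,
                    wbc_ingestion_mgy="" if r.wbc_ingestion_mgy is None else r.wbc_ingestion_mgy,
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "parent_id", "settlement_id", "start_date", "end_date",
            "house_type", "zone", "wbc_ingestion_mgy",
        ],
    ).to_csv(out / "residence.csv", index=False)

    rows = [
        dict(
            settlement_id=sid,
            country=s.country,
            cs137_kbq_m2=s.cs137_kbq_m2,
            area_id=s.area_id,
        )
        for sid, s in sorted(bundle.settlements.items())
    ]
    pd.DataFrame(rows).to_csv(out / "settlements.csv", index=False)

    rows = []
    for pid in sorted(bundle.diets):
        d = bundle.diets[pid]
        for food in FOODS:
            if food not in d.rates:
                continue
            rate = d.rates[food]
            rows.append(
                dict(
                    parent_id=pid,
                    foodstuff=food,
                    rate_am="" if (isinstance(rate, float) and math.isnan(rate)) else rate,
                    unit="L_per_day" if food == "milk" else "kg_per_day",
                    source=d.source(food),
                )
            )
    pd.DataFrame(
        rows, columns=["parent_id", "foodstuff", "rate_am", "unit", "source"]
    ).to_csv(out / "diet.csv", index=False)

    manifest = {
        "seed": bundle.seed,
        "n_trios": len(bundle.trios),
        "n_children": len(bundle.children),
        "files": {name: _sha256(out / name) for name in BUNDLE_FILES},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# readers


def _date(s: str) -> _dt.date:
    return _dt.date.fromisoformat(str(s))


def read_bundle(in_dir) -> CohortBundle:
    """Read a bundle directory back into memory (inverse of ``write_bundle``)."""
    p = Path(in_dir)
    cohort = pd.read_csv(p / "cohort.csv", dtype=str)
    parents_df = pd.read_csv(p / "parents.csv")
    itin_df = pd.read_csv(p / "itinerary.csv", float_precision="round_trip")
    akr_df = pd.read_csv(p / "akr_grid.csv", dtype={"location_id": str}, float_precision="round_trip")
    prip_df = pd.read_csv(p / "pripyat.csv", float_precision="round_trip")
    res_df = pd.read_csv(p / "residence.csv", float_precision="round_trip")
    set_df = pd.read_csv(p / "settlements.csv", dtype={"settlement_id": str}, float_precision="round_trip")
    diet_df = pd.read_csv(p / "diet.csv", float_precision="round_trip")

    children, trios = [], {}
    for _, row in cohort.iterrows():
        children.append(
            Child(id=row.child_id, trio_id=row.trio_id, dob=_date(row.dob))
        )
        if row.trio_id not in trios:
            trios[row.trio_id] = dict(
                id=row.trio_id,
                category=row.category,
                father_id=row.father_id,
                mother_id=row.mother_id,
                child_ids=[],
            )
        trios[row.trio_id]["child_ids"].append(row.child_id)
    trio_objs = [
        Trio(
            id=t["id"], category=t["category"], father_id=t["father_id"],
            mother_id=t["mother_id"], child_ids=tuple(t["child_ids"]),
        )
        for t in trios.values()
    ]

    parents = {}
    for _, row in parents_df.iterrows():
        paths = frozenset(
            pw for pw, flag in _PATHWAY_FLAGS.items() if int(row[flag])
        )
        parents[row.parent_id] = Parent(
            id=row.parent_id, sex=Sex(row.sex), pathways=paths
        )

    itineraries: dict[str, list[ItineraryEntry]] = {}
    for _, row in itin_df.iterrows():
        itineraries.setdefault(row.parent_id, []).append(
            ItineraryEntry(
                day=_date(row.day),
                location_id=str(row.location_id),
                activity=str(row.activity),
                duration=duration_spec(float(row.duration_am_h), float(row.duration_cv)),
                lf=lf_spec_site(float(row.lf_am)),
            )
        )

    grid = AkrGrid()
    for _, row in akr_df.iterrows():
        gsd = float(row.akr_gsd)
        gm = gm_from_am_gsd(float(row.akr_am_mGy_h), gsd)
        grid.add(
            str(row.location_id),
            _date(row.date),
            trunclognorm(gm, gsd, gm / gsd**2, gm * gsd**2),
        )

    pripyat: dict[str, list[PripyatEntry]] = {}
    for _, row in prip_df.iterrows():
        gm, gsd = float(row.akr_gm), float(row.akr_gsd)
        pripyat.setdefault(row.parent_id, []).append(
            PripyatEntry(
                start_hour=float(row.start_hour),
                end_hour=float(row.end_hour),
                location_kind=str(row.location_kind),
                akr=trunclognorm(gm, gsd, gm / gsd**2, gm * gsd**2),
                lf=lf_spec_pripyat(float(row.lf_gm)),
                building_id=None if pd.isna(row.building_id) or row.building_id == "" else str(row.building_id),
                floor=None if pd.isna(row.floor) else int(row.floor),
            )
        )

    residences: dict[str, list[ResidenceRecord]] = {}
    for _, row in res_df.iterrows():
        wbc = row.get("wbc_ingestion_mgy")
        residences.setdefault(row.parent_id, []).append(
            ResidenceRecord(
                parent_id=row.parent_id,
                settlement_id=str(row.settlement_id),
                start=_date(row.start_date),
                end=_date(row.end_date),
                house_type=str(row.house_type),
                zone=str(row.zone),
                wbc_ingestion_mgy=None if pd.isna(wbc) or wbc == "" else float(wbc),
            )
        )

    settlements = {
        str(row.settlement_id): SettlementRecord(
            id=str(row.settlement_id),
            country=str(row.country),
            cs137_kbq_m2=float(row.cs137_kbq_m2),
            area_id=str(row.area_id),
        )
        for _, row in set_df.iterrows()
    }

    diets: dict[str, DietRecord] = {}
    rates: dict[str, dict] = {}
    sources: dict[str, dict] = {}
    for _, row in diet_df.iterrows():
        rates.setdefault(row.parent_id, {})[row.foodstuff] = (
            float("nan") if pd.isna(row.rate_am) else float(row.rate_am)
        )
        if not pd.isna(row.source):
            sources.setdefault(row.parent_id, {})[row.foodstuff] = str(row.source)
    for pid in rates:
        diets[pid] = DietRecord(
            parent_id=pid, rates=rates[pid], sources=sources.get(pid, {})
        )

    manifest_path = p / "manifest.json"
    seed = 0
    if manifest_path.exists():
        seed = json.loads(manifest_path.read_text()).get("seed", 0)

    return CohortBundle(
        trios=trio_objs,
        children=children,
        parents=parents,
        itineraries=itineraries,
        akr_grid=grid,
        pripyat_timelines=pripyat,
        residences=residences,
        settlements=settlements,
        diets=diets,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# validation


def validate_bundle(in_dir) -> list[str]:
    """Per-file, per-row error list; empty for a valid bundle."""
    p = Path(in_dir)
    errors: list[str] = []
    for name in BUNDLE_FILES:
        if not (p / name).exists():
            errors.append(f"{name}: file missing")
    if errors:
        return errors
    try:
        bundle = read_bundle(p)
    except Exception as exc:  # unreadable/unparseable file is fatal
        return [f"bundle unreadable: {exc}"]

    parent_ids = set(bundle.parents)
    for t in bundle.trios:
        for pid in (t.father_id, t.mother_id):
            if pid not in parent_ids:
                errors.append(f"cohort.csv: trio {t.id} references unknown parent {pid}")
    for ch in bundle.children:
        if not is_eligible(ch.dob):
            errors.append(f"cohort.csv: child {ch.id} DOB {ch.dob} not eligible")

    grid_locs = set(bundle.akr_grid.locations())
    for pid, entries in bundle.itineraries.items():
        if pid not in parent_ids:
            errors.append(f"itinerary.csv: unknown parent {pid}")
        for e in entries:
            if e.location_id not in grid_locs:
                errors.append(
                    f"itinerary.csv: {pid} references missing location {e.location_id}"
                )

    for pid, recs in bundle.residences.items():
        if pid not in parent_ids:
            errors.append(f"residence.csv: unknown parent {pid}")
        ordered = sorted(recs, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                errors.append(
                    f"residence.csv: {pid} intervals overlap at {b.start}"
                )
        for r in recs:
            if r.settlement_id not in bundle.settlements:
                errors.append(
                    f"residence.csv: {pid} references unknown settlement {r.settlement_id}"
                )

    for pid, entries in bundle.pripyat_timelines.items():
        ordered = sorted(entries, key=lambda e: e.start_hour)
        for a, b in zip(ordered, ordered[1:]):
            if b.start_hour < a.end_hour - 1e-9:
                errors.append(
                    f"pripyat.csv: {pid} timeline entries overlap at hour {b.start_hour}"
                )
    return errors


# ---------------------------------------------------------------------------
# parameter library


def default_parameter_library(gm_printed_form: bool = False) -> dict:
    """Every distribution family used by the engines, keyed by parameter id,
    with sharing scope and a provenance note."""
    lib: dict[str, dict] = {}

    def add(pid, spec, shared, provenance):
        lib[pid] = {
            "spec": spec.to_dict(),
            "shared": shared,
            "provenance": provenance,
        }

    add("cg_male", cg_spec(Sex.MALE), "unshared",
        "air-kerma to testes dose conversion, isotropic 0.3 MeV")
    add("cg_female", cg_spec(Sex.FEMALE), "unshared",
        "air-kerma to ovaries dose conversion, isotropic 0.3 MeV")
    add("site_lf_unit", lf_spec_site(1.0), "unshared",
        "cleanup-site location factor family (per-entry AM)")
    add("pripyat_lf_unit", lf_spec_pripyat(1.0), "unshared",
        "Pripyat location factor family (per-location GM)")
    add("duration_unit", duration_spec(1.0, 0.1), "unshared",
        "itinerary task duration family (per-entry AM, CV)")
    for ht in HOUSE_TYPES:
        for zone in ("30km", "other"):
            add(f"bf_{ht}_{zone}", behaviour_factor_spec(ht, zone), "global",
                "behaviour factor: occupancy-weighted shielding")
    for pid, spec in AttenuationParams.specs().items():
        add(f"atten_{pid}", spec, "global",
            "two-exponential soil-migration attenuation")
    add("iv", iv_spec(), "unshared", "individual outdoor-time variability")
    for food in FOODS:
        add(f"cf_{food}", cf_spec(food), "global",
            "foodstuff-to-milk cesium conversion factor")
    add("cf_milk_shop", cf_spec("milk", "shop"), "global",
        "shop milk to private milk cesium conversion factor")
    ip = IntakeParams()
    add("c86_scale", ip.c86_scale_spec, "global",
        "pasture-period milk concentration scale")
    add("rel_scale", ip.rel_scale_spec, "global",
        "root-uptake-period relative concentration scale")
    add("tf_unit", ip.tf_spec(), "settlement",
        "soil-to-milk transfer family (per-settlement AM)")
    add("sigma_ukraine_unit", deposition_spec(1.0, "Ukraine"), "settlement",
        "deposition density family, Ukraine / low-deposition Belarus")
    add("sigma_russia_unit", deposition_spec(1.0, "Russia"), "settlement",
        "deposition density family, Russia / high-deposition Belarus")
    lib["_meta"] = {
        "gm_from_am_formula": "printed" if gm_printed_form else "standard",
        "df_central_mgy_per_bq": DEFAULT_DF,
    }
    return lib


def parameter_library_checksum(lib: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(lib, sort_keys=True).encode()
    ).hexdigest()


def write_parameter_library(lib: Mapping, path) -> None:
    Path(path).write_text(json.dumps(lib, indent=2, sort_keys=True))


def load_parameter_library(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    n_mission: int = 10_000
    n_residential: int = 1_000
    seed: int = 0
    gm_printed_form: bool = False
    windows: tuple[WindowKind, ...] = (WindowKind.DOB51, WindowKind.DOB38)


@dataclass
class PipelineResult:
    doses: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    crosstabs: dict[str, np.ndarray]
    correlations: dict[str, tuple[float, float]]
    manifest: dict
    realizations: dict[tuple, StochasticDoses] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.doses.to_csv(out / "doses.csv", index=False)
        for name, df in self.summaries.items():
            df.to_csv(out / f"summary_{name}.csv", index=False)
        for name, mat in self.crosstabs.items():
            pd.DataFrame(mat).to_csv(out / f"crosstab_{name}.csv", index=False)
        (out / "run_manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True)
        )


def run_pipeline(
    bundle: CohortBundle, config: PipelineConfig | None = None
) -> PipelineResult:
    """Compute every pathway dose for every child x parent x window.

    Mission and Pripyat realizations use plain Monte Carlo with all-unshared
    parameters (a parent holding both records has them merged into the
    cleanup-mission pathway); residential external and ingestion doses run
    through the 2-D Monte Carlo with shared/unshared separation.  Common
    random numbers couple the two windows of each subject.
    """
    config = config or PipelineConfig()
    if config.n_mission < 1 or config.n_residential < 1:
        raise ValueError("realization counts must be positive")
    trio_by_id = {t.id: t for t in bundle.trios}
    rows = []
    realizations: dict[tuple, StochasticDoses] = {}

    # --- residential pathways: one 2D-MC run per window and pathway
    resid_results: dict[tuple[str, str, Pathway], StochasticDoses] = {}
    for kind in config.windows:
        subjects = []
        for ch in bundle.children:
            t = trio_by_id[ch.trio_id]
            for pid in (t.father_id, t.mother_id):
                parent = bundle.parents[pid]
                if not bundle.residences.get(pid):
                    continue
                subjects.append(
                    ResidentialSubject(
                        id=f"{pid}|{ch.id}",
                        rng_id=pid,
                        sex=parent.sex,
                        window=ch.window(kind),
                        residences=bundle.residences[pid],
                        diet=bundle.diets.get(pid),
                    )
                )
        for pathway in (Pathway.RESIDENTIAL_EXTERNAL, Pathway.RESIDENTIAL_INGESTION):
            result = run_2d_mc(
                subjects,
                bundle.settlements,
                pathway,
                n_sets=config.n_residential,
                seed=config.seed,
            )
            for sid, doses in result.items():
                pid, cid = sid.split("|")
                resid_results[(pid, cid, kind, pathway)] = doses

    # --- per child x parent rows
    for ch in sorted(bundle.children, key=lambda c: c.id):
        t = trio_by_id[ch.trio_id]
        for role, pid in (("father", t.father_id), ("mother", t.mother_id)):
            parent = bundle.parents[pid]
            for kind in config.windows:
                window = ch.window(kind)
                pathway_values: dict[Pathway, StochasticDoses] = {}

                itinerary = bundle.itineraries.get(pid)
                if itinerary:
                    mission_end = max(e.day for e in itinerary) + _dt.timedelta(days=1)
                    cutoff = mission_cutoff(window.end, mission_end)
                    doses = run_unshared_mc(
                        pid,
                        parent.sex,
                        Pathway.MISSION,
                        n=config.n_mission,
                        seed=config.seed,
                        itinerary=itinerary,
                        akr_grid=bundle.akr_grid,
                        cutoff=cutoff,
                        window_kind=kind,
                    )
                    pathway_values[Pathway.MISSION] = doses

                occupancy = bundle.pripyat_timelines.get(pid)
                if occupancy:
                    cutoff_hour = 24.0 * window.length_days
                    doses = run_unshared_mc(
                        pid,
                        parent.sex,
                        Pathway.PRIPYAT,
                        n=config.n_mission,
                        seed=config.seed,
                        occupancy=occupancy,
                        cutoff_hour=cutoff_hour,
                        window_kind=kind,
                    )
                    # a cleanup worker resident in Pripyat has the residence
                    # dose folded into the mission pathway
                    if Pathway.MISSION in pathway_values:
                        merged = pathway_values[Pathway.MISSION]
                        merged.values = merged.values + doses.values
                    else:
                        pathway_values[Pathway.PRIPYAT] = doses

                for pathway in (
                    Pathway.RESIDENTIAL_EXTERNAL,
                    Pathway.RESIDENTIAL_INGESTION,
                ):
                    key = (pid, ch.id, kind, pathway)
                    if key in resid_results:
                        pathway_values[pathway] = resid_results[key]

                for pathway, doses in pathway_values.items():
                    central = doses.central() if doses.n else 0.0
                    try:
                        gsd = doses.gsd() if doses.n else float("nan")
                    except ValueError:
                        gsd = float("nan")
                    rows.append(
                        dict(
                            child_id=ch.id,
                            parent_id=pid,
                            parent_role=role,
                            pathway=pathway.value,
                            window=kind.value,
                            central_mGy=central,
                            gsd=gsd,
                            n_realizations=doses.n,
                            seed=config.seed,
                        )
                    )
                    realizations[(pid, ch.id, kind.value, pathway.value)] = doses

    doses_df = pd.DataFrame(
        rows,
        columns=[
            "child_id", "parent_id", "parent_role", "pathway", "window",
            "central_mGy", "gsd", "n_realizations", "seed",
        ],
    )

    summaries, crosstabs, correlations = summarize_doses(doses_df, bundle)

    lib = default_parameter_library(config.gm_printed_form)
    manifest = {
        "seed": config.seed,
        "n_mission": config.n_mission,
        "n_residential": config.n_residential,
        "n_trios": len(bundle.trios),
        "n_children": len(bundle.children),
        "gm_from_am_formula": "printed" if config.gm_printed_form else "standard",
        "parameter_library_sha256": parameter_library_checksum(lib),
        "bundle_seed": bundle.seed,
    }
    return PipelineResult(
        doses=doses_df,
        summaries=summaries,
        crosstabs=crosstabs,
        correlations=correlations,
        manifest=manifest,
        realizations=realizations,
    )


def child_totals(doses_df: pd.DataFrame, role: str, window: str) -> dict[str, float]:
    """Per-child total dose (sum of pathway central estimates) for one role."""
    sub = doses_df[(doses_df.parent_role == role) & (doses_df.window == window)]
    return sub.groupby("child_id")["central_mGy"].sum().to_dict()


def summarize_doses(doses_df: pd.DataFrame, bundle: CohortBundle):
    """Reporting tables from a per-child dose table."""
    summaries: dict[str, pd.DataFrame] = {}
    crosstabs: dict[str, np.ndarray] = {}
    correlations: dict[str, tuple[float, float]] = {}
    dob_by_child = {ch.id: ch.dob for ch in bundle.children}

    for role in ("father", "mother"):
        totals38 = child_totals(doses_df, role, WindowKind.DOB38.value)
        totals51 = child_totals(doses_df, role, WindowKind.DOB51.value)
        # every child appears, with zero for absent pathways
        for cid in dob_by_child:
            totals38.setdefault(cid, 0.0)
            totals51.setdefault(cid, 0.0)
        summaries[f"total_{role}"] = pathway_summary(totals38, include_zero=True)
        if totals51:
            crosstabs[role] = crosstab_windows(totals51, totals38)
        sub38 = doses_df[
            (doses_df.parent_role == role)
            & (doses_df.window == WindowKind.DOB38.value)
        ]
        for pathway in Pathway:
            pw = sub38[sub38.pathway == pathway.value]
            if len(pw):
                summaries[f"{pathway.value}_{role}"] = pathway_summary(
                    dict(zip(pw.child_id, pw.central_mGy)), include_zero=False
                )
                nonzero = pw[(pw.central_mGy > 0) & np.isfinite(pw.gsd)]
                if len(nonzero):
                    summaries[f"gsd_{pathway.value}_{role}"] = gsd_table(
                        dict(zip(nonzero.child_id, nonzero.gsd)),
                        dict(zip(nonzero.child_id, nonzero.central_mGy)),
                    )
        if len(totals38) >= 3:
            years = [dob_by_child[cid].year for cid in totals38]
            values = list(totals38.values())
            for scale in ("linear", "log"):
                try:
                    correlations[f"{role}_{scale}"] = dose_birthyear_correlation(
                        values, years, scale=scale
                    )
                except ValueError:
                    pass
    return summaries, crosstabs, correlations
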