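"""Monte Carlo orchestration: plain MC for the time-and-motion pathways,
two-dimensional MC with shared/unshared separation for the residential ones.

Mission and Pripyat doses carry only unshared (subject-dependent) parameter
errors, so their realizations are plain Monte Carlo through the
time-and-motion kernels.  Residential external and ingestion doses mix
parameters whose errors are shared across subjects — the settlement's
deposition density and soil-to-milk transfer (shared per settlement), the
deposition ratios (shared per area), behaviour factors, attenuation and
conversion factors (shared globally) — with unshared ones (individual
variability, consumption rates, dose factors).  The 2-D scheme draws one
value per shared parameter per realization *set*, applies it to every
subject that resolves the same scope key, then draws the unshared
parameters per subject within the set.

Common random numbers are used across the DOB-51 and DOB-38 windows of the
same subject (identical substreams), so the window-nesting inequality
DOB-38 dose >= DOB-51 dose holds realization by realization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _stats

from .core import (
    ExposureWindow,
    Pathway,
    PathwayDose,
    Sex,
    StochasticDoses,
    WindowKind,
    total_dose,
)
from .distributions import RngStream
from .ingestion import (
    DietRecord,
    FOODS,
    ISOTOPES,
    IntakeParams,
    cf_spec,
    consumption_spec,
    dose_factor_spec,
    DEFAULT_DF,
)
from .mission import AkrGrid, ItineraryEntry, PripyatEntry, cg_spec
from .nuclides import RATIO_CORRELATION, NuclideRecord, default_inventory
from .resexternal import (
    AttenuationParams,
    ResidenceRecord,
    SettlementRecord,
    behaviour_factor_spec,
    iv_spec,
    residential_external_dose,
)
from .ingestion import ingestion_dose

#: Default realization counts: 10 000 for the time-and-motion pathways,
#: 1000 sets for the residential 2-D scheme.
N_MISSION_DEFAULT = 10_000
N_RESIDENTIAL_DEFAULT = 1_000


@dataclass
class ResidentialSubject:
    """One parent x child-window residential exposure case.

    ``rng_id`` keys the unshared-parameter substreams; giving two cases
    (e.g. the DOB-51 and DOB-38 windows of the same parent) the same
    ``rng_id`` couples them with common random numbers.
    """

    id: str
    sex: Sex
    window: ExposureWindow
    residences: Sequence[ResidenceRecord]
    diet: Optional[DietRecord] = None
    rng_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rng_id is None:
            self.rng_id = self.id


@dataclass
class SharedParameterSet:
    """Realized shared-parameter vectors, keyed by scope.

    Every array has length ``n_sets``; within set ``s`` all subjects
    resolving the same scope key read the identical element ``s``.
    """

    n_sets: int
    sigma: dict[str, np.ndarray] = field(default_factory=dict)  # settlement -> draws
    tf: dict[str, np.ndarray] = field(default_factory=dict)  # settlement -> draws
    ratios: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)  # area ->
    bf: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    atten: Optional[AttenuationParams] = None
    cf: dict[str, np.ndarray] = field(default_factory=dict)  # food -> draws
    c86_scale: np.ndarray | float = 1.0
    rel_scale: np.ndarray | float = 1.0


def sample_ratio_sets(
    inventory: Mapping[str, NuclideRecord],
    rng: np.random.Generator,
    n: int,
) -> dict[str, np.ndarray]:
    """Draw one deposition-ratio vector per nuclide, honouring the stated
    pairwise copula correlations (a dependency tree anchored at the
    uncorrelated nuclides)."""
    z: dict[str, np.ndarray] = {}

    def z_for(name: str) -> np.ndarray:
        if name in z:
            return z[name]
        link = RATIO_CORRELATION.get(name)
        if link is None:
            z[name] = rng.standard_normal(n)
        else:
            anchor, r = link
            za = z_for(anchor)
            z[name] = r * za + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
        return z[name]

    out = {}
    # draw in sorted order so the sequence is independent of dict ordering
    for name in sorted(inventory):
        rec = inventory[name]
        if rec.ratio_spec.family == "point":
            out[name] = np.full(n, rec.ratio_spec.central())
        else:
            out[name] = rec.ratio_spec.ppf(_stats.norm.cdf(z_for(name)))
    return out


def draw_shared_set(
    subjects: Sequence[ResidentialSubject],
    settlements: Mapping[str, SettlementRecord],
    n_sets: int,
    stream: RngStream,
    inventory: Mapping[str, NuclideRecord] | None = None,
    intake_params: IntakeParams | None = None,
) -> SharedParameterSet:
    """One draw of every shared parameter per realization set."""
    inventory = inventory or default_inventory()
    intake_params = intake_params or IntakeParams()
    shared = SharedParameterSet(n_sets=n_sets)

    needed_settlements = sorted(
        {r.settlement_id for s in subjects for r in s.residences}
    )
    for sid in needed_settlements:
        if sid not in settlements:
            raise KeyError(f"residence references unknown settlement {sid!r}")
        st = settlements[sid]
        shared.sigma[sid] = st.sigma_spec.sample(
            stream.stream("shared", "sigma", sid), n_sets
        )
        shared.tf[sid] = intake_params.tf_spec().sample(
            stream.stream("shared", "tf", sid), n_sets
        )

    for area in sorted({settlements[sid].area_id for sid in needed_settlements}):
        shared.ratios[area] = sample_ratio_sets(
            inventory, stream.stream("shared", "ratios", area), n_sets
        )

    for ht_zone in sorted(
        {(r.house_type, r.zone) for s in subjects for r in s.residences}
    ):
        shared.bf[ht_zone] = behaviour_factor_spec(*ht_zone).sample(
            stream.stream("shared", "bf", *ht_zone), n_sets
        )

    a_specs = AttenuationParams.specs()
    shared.atten = AttenuationParams(
        p1=a_specs["p1"].sample(stream.stream("shared", "atten", "p1"), n_sets),
        lambda1=a_specs["lambda1"].sample(
            stream.stream("shared", "atten", "l1"), n_sets
        ),
        lambda2=a_specs["lambda2"].sample(
            stream.stream("shared", "atten", "l2"), n_sets
        ),
    )
    for food in FOODS:
        shared.cf[food] = cf_spec(food).sample(
            stream.stream("shared", "cf", food), n_sets
        )
    shared.cf["milk_shop"] = cf_spec("milk", "shop").sample(
        stream.stream("shared", "cf", "milk_shop"), n_sets
    )
    shared.c86_scale = intake_params.c86_scale_spec.sample(
        stream.stream("shared", "c86"), n_sets
    )
    shared.rel_scale = intake_params.rel_scale_spec.sample(
        stream.stream("shared", "rel"), n_sets
    )
    return shared


def run_2d_mc(
    subjects: Sequence[ResidentialSubject],
    settlements: Mapping[str, SettlementRecord],
    pathway: Pathway,
    n_sets: int = N_RESIDENTIAL_DEFAULT,
    seed: int = 0,
    inventory: Mapping[str, NuclideRecord] | None = None,
    intake_params: IntakeParams | None = None,
    shared: SharedParameterSet | None = None,
) -> dict[str, StochasticDoses]:
    """Two-dimensional Monte Carlo over a residential pathway.

    Outer dimension: ``n_sets`` shared-parameter sets; inner: per-subject
    unshared draws.  Returns one :class:`StochasticDoses` per subject with
    ``n_sets`` realizations.  Within any set, two subjects resident in the
    same settlement see the identical realized deposition density and
    soil-to-milk transfer.
    """
    if pathway not in (Pathway.RESIDENTIAL_EXTERNAL, Pathway.RESIDENTIAL_INGESTION):
        raise ValueError(f"2D MC applies to residential pathways, not {pathway}")
    inventory = inventory or default_inventory()
    intake_params = intake_params or IntakeParams()
    stream = RngStream(seed)
    if shared is None:
        shared = draw_shared_set(
            subjects, settlements, n_sets, stream, inventory, intake_params
        )

    out: dict[str, StochasticDoses] = {}
    for subj in subjects:
        dose = np.zeros(n_sets)
        if pathway is Pathway.RESIDENTIAL_EXTERNAL:
            iv = iv_spec().sample(stream.stream(subj.rng_id, "iv"), n_sets)
            for ridx, rec in enumerate(subj.residences):
                st = settlements[rec.settlement_id]
                dose += residential_external_dose(
                    rec,
                    st,
                    subj.window,
                    subj.sex,
                    sigma=shared.sigma[rec.settlement_id],
                    ratios=shared.ratios[st.area_id],
                    bf=shared.bf[(rec.house_type, rec.zone)],
                    iv=iv,
                    atten=shared.atten,
                    inventory=inventory,
                )
        else:
            rates = {}
            if subj.diet is not None:
                for food in FOODS:
                    rates[food] = consumption_spec(
                        food, subj.diet.rate(food)
                    ).sample(stream.stream(subj.rng_id, "rate", food), n_sets)
            df = {
                k: dose_factor_spec(DEFAULT_DF[k][subj.sex.value]).sample(
                    stream.stream(subj.rng_id, "df", k), n_sets
                )
                for k in ISOTOPES
            }
            cf = dict(shared.cf)
            if subj.diet is not None and subj.diet.source("milk") == "shop":
                cf["milk"] = shared.cf["milk_shop"]
            for rec in subj.residences:
                dose += np.asarray(
                    ingestion_dose(
                        rec,
                        subj.diet,
                        settlements[rec.settlement_id],
                        intake_params,
                        subj.window,
                        subj.sex,
                        sigma=shared.sigma[rec.settlement_id],
                        cf=cf,
                        rates=rates if subj.diet is not None else None,
                        df=df,
                        c86_scale=shared.c86_scale,
                        rel_scale=shared.rel_scale,
                        tf=shared.tf[rec.settlement_id],
                    )
                ) * np.ones(n_sets)
        out[subj.id] = StochasticDoses(
            subject_id=subj.id,
            pathway=pathway,
            window_kind=subj.window.kind,
            values=dose,
            seed=seed,
        )
    return out


def run_unshared_mc(
    subject_id: str,
    sex: Sex,
    pathway: Pathway,
    n: int = N_MISSION_DEFAULT,
    seed: int = 0,
    itinerary: Sequence[ItineraryEntry] | None = None,
    akr_grid: AkrGrid | None = None,
    cutoff=None,
    occupancy: Sequence[PripyatEntry] | None = None,
    cutoff_hour: Optional[float] = None,
    window_kind: WindowKind = WindowKind.DOB38,
) -> StochasticDoses:
    """Plain (all-unshared) Monte Carlo for a time-and-motion pathway.

    An absent pathway (no itinerary/occupancy) returns an empty result
    flagged as a structural zero.
    """
    from .mission import mission_dose_stochastic, pripyat_dose

    stream = RngStream(seed)
    if pathway is Pathway.MISSION:
        if not itinerary:
            return StochasticDoses(
                subject_id, pathway, window_kind, np.array([]), seed, True
            )
        return mission_dose_stochastic(
            itinerary,
            akr_grid,
            cg_spec(sex),
            cutoff,
            n=n,
            stream=stream,
            subject_id=subject_id,
            window_kind=window_kind,
        )
    if pathway is Pathway.PRIPYAT:
        if not occupancy:
            return StochasticDoses(
                subject_id, pathway, window_kind, np.array([]), seed, True
            )
        return pripyat_dose(
            occupancy,
            cg_spec(sex),
            n=n,
            stream=stream,
            subject_id=subject_id,
            window_kind=window_kind,
            cutoff_hour=cutoff_hour,
        )
    raise ValueError(f"plain MC applies to mission/Pripyat, not {pathway}")


def central_estimate(doses: StochasticDoses) -> float:
    """Arithmetic mean of the realizations — the central dose estimate."""
    return doses.central()


def total_parent_dose(pathway_doses: Sequence[PathwayDose]) -> float:
    """Sum of pathway central estimates (missing pathways contribute zero)."""
    return total_dose(pathway_doses)
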