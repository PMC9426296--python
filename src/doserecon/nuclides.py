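"""Radionuclide inventory for residential ground-shine dosimetry.

Seventeen gamma-emitting fission/activation products dominate external
exposure from Chornobyl ground deposits; Te-131m and I-135 are carried in
the configurable inventory as well.  Each nuclide record holds

* a decay constant (1/day) from a standard half-life table,
* a deposition-activity ratio to Cs-137 at the accident date, as a
  triangular uncertainty spec with area-level sharing and, for some
  pairs, a copula correlation to a group anchor,
* sex-specific gonadal dose-rate coefficients DC (mGy/day per kBq/m2 of
  areal activity), and
* an optional decay parent (Nb-95, I-132 and La-140 grow in from Zr-95,
  Te-132 and Ba-140; their areal activity follows the two-member Bateman
  solution).

The deposition-ratio central values and the DC table are documented
placeholder values of realistic magnitude (the field databases behind
them are not public); both are overridable through a JSON config, and
the package's verification suite is constructed to be independent of
their absolute magnitudes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Optional

from .core import Sex
from .distributions import DistributionSpec, triangular

_LN2 = math.log(2.0)
_DAY_Y = 365.25
_DAY_H = 1.0 / 24.0

#: Half-lives in days, from standard decay data.
HALF_LIFE_DAYS: dict[str, float] = {
    "Zr-95": 64.03,
    "Nb-95": 34.99,
    "Mo-99": 65.98 * _DAY_H,
    "Ru-103": 39.25,
    "Ru-106": 371.8,
    "Te-131m": 33.25 * _DAY_H,
    "Te-132": 3.20,
    "I-131": 8.02,
    "I-132": 2.30 * _DAY_H,
    "I-133": 20.83 * _DAY_H,
    "I-135": 6.58 * _DAY_H,
    "Cs-134": 2.065 * _DAY_Y,
    "Cs-136": 13.16,
    "Cs-137": 30.05 * _DAY_Y,
    "Ba-140": 12.75,
    "La-140": 1.678,
    "Ce-141": 32.5,
    "Ce-144": 284.9,
    "Np-239": 2.356,
}

#: Decay parents for in-growing daughters.
PARENT_OF = {"Nb-95": "Zr-95", "I-132": "Te-132", "La-140": "Ba-140"}

#: Placeholder deposition-activity ratios to Cs-137 at the accident date
#: (condensed-component fallout magnitudes; configurable).
DEFAULT_RATIO_AM: dict[str, float] = {
    "Zr-95": 1.6,
    "Nb-95": 1.6,
    "Mo-99": 2.0,
    "Ru-103": 3.3,
    "Ru-106": 0.8,
    "Te-131m": 1.0,
    "Te-132": 8.0,
    "I-131": 10.0,
    "I-132": 8.3,
    "I-133": 5.0,
    "I-135": 2.0,
    "Cs-134": 0.5,
    "Cs-136": 0.3,
    "Cs-137": 1.0,
    "Ba-140": 2.8,
    "La-140": 2.8,
    "Ce-141": 1.4,
    "Ce-144": 1.0,
    "Np-239": 10.0,
}

# Triangular half-width class per nuclide (fraction of AM), and copula
# correlation (anchor nuclide, r) where a pairing is stated.
_RATIO_WIDTH: dict[str, float] = {
    "Zr-95": 0.2, "Nb-95": 0.2, "Ce-141": 0.2, "Ce-144": 0.2,
    "Mo-99": 0.25, "Ru-103": 0.25, "Ru-106": 0.25, "Ba-140": 0.25,
    "La-140": 0.25, "Np-239": 0.25,
    "Te-131m": 0.15, "Te-132": 0.15, "I-131": 0.15, "I-132": 0.15,
    "I-133": 0.15, "I-135": 0.15,
}
RATIO_CORRELATION: dict[str, tuple[str, float]] = {
    "Nb-95": ("Zr-95", 0.95),
    "Ce-141": ("Ce-144", 0.9),
    "Ce-144": ("Zr-95", 0.95),
    "Ru-106": ("Ru-103", 0.9),
    "Ba-140": ("La-140", 0.95),
    "I-132": ("Te-132", 0.95),
    "I-133": ("I-131", 0.9),
    "I-135": ("I-131", 0.9),
}

#: Cs-134 and Cs-136 ride the sampled Cs-137 deposition deterministically
#: (fixed initial activity ratios; correlation 1.0 with the deposition draw).
CESIUM_FIXED_RATIO = ("Cs-134", "Cs-136")

# Placeholder gonadal dose-rate coefficients: proportional to the total
# gamma energy emitted per decay, scaled so the Cs-137 value lands at the
# ~6e-5 mGy/day per kBq/m2 magnitude expected for fresh surface deposition
# (1 Ci/km^2 ~ 0.1 uGy/h in air); ovaries get an extra 0.85 depth-shielding
# factor.  Configurable; verification never relies on the absolute values.
_GAMMA_MEV: dict[str, float] = {
    "Zr-95": 0.74, "Nb-95": 0.77, "Mo-99": 0.15, "Ru-103": 0.49,
    "Ru-106": 0.20, "Te-131m": 1.40, "Te-132": 0.23, "I-131": 0.38,
    "I-132": 2.20, "I-133": 0.60, "I-135": 1.60, "Cs-134": 1.55,
    "Cs-136": 2.20, "Cs-137": 0.60, "Ba-140": 0.18, "La-140": 2.30,
    "Ce-141": 0.08, "Ce-144": 0.02, "Np-239": 0.17,
}
_DC_SCALE = 1.0e-4
_OVARY_FACTOR = 0.85


@dataclass(frozen=True)
class NuclideRecord:
    name: str
    decay_const: float  # 1/day
    ratio_spec: DistributionSpec  # deposition ratio to Cs-137 at t=0
    dc: Mapping[str, float]  # sex -> mGy/day per kBq/m2
    parent: Optional[str] = None
    fixed_ratio: bool = False  # rides the Cs-137 deposition draw exactly

    def __post_init__(self) -> None:
        if self.decay_const <= 0:
            raise ValueError(f"{self.name}: decay constant must be positive")

    @property
    def half_life_days(self) -> float:
        return _LN2 / self.decay_const

    def dc_for(self, sex: Sex) -> float:
        return self.dc[sex.value]


def _ratio_spec(name: str, am: float) -> DistributionSpec:
    if name == "Cs-137":
        return DistributionSpec("point", {"value": 1.0})
    if name in CESIUM_FIXED_RATIO:
        return DistributionSpec("point", {"value": am})
    w = _RATIO_WIDTH[name]
    corr = RATIO_CORRELATION.get(name)
    return triangular(
        (1 - w) * am, am, (1 + w) * am,
        corr_group="deposition_ratios",
        r=None if corr is None else corr[1],
    )


def default_inventory() -> dict[str, NuclideRecord]:
    """The full nuclide inventory with default half-lives, ratios and DCs."""
    inv: dict[str, NuclideRecord] = {}
    for name, hl in HALF_LIFE_DAYS.items():
        am = DEFAULT_RATIO_AM[name]
        dc_m = _GAMMA_MEV[name] * _DC_SCALE
        inv[name] = NuclideRecord(
            name=name,
            decay_const=_LN2 / hl,
            ratio_spec=_ratio_spec(name, am),
            dc={"male": dc_m, "female": dc_m * _OVARY_FACTOR},
            parent=PARENT_OF.get(name),
            fixed_ratio=(name in CESIUM_FIXED_RATIO or name == "Cs-137"),
        )
    return inv


def load_inventory(path) -> dict[str, NuclideRecord]:
    """Inventory from a JSON config overriding any subset of the defaults.

    Schema per nuclide: {"half_life_days": x, "ratio": spec-or-number,
    "dc": {"male": x, "female": x}, "parent": name-or-null}.
    """
    with open(path) as fh:
        cfg = json.load(fh)
    inv = default_inventory()
    for name, entry in cfg.items():
        base = inv.get(name)
        hl = entry.get("half_life_days", None)
        lam = _LN2 / hl if hl else (base.decay_const if base else None)
        if lam is None:
            raise ValueError(f"{name}: half_life_days required for new nuclide")
        ratio = entry.get("ratio")
        if ratio is None:
            rspec = base.ratio_spec if base else DistributionSpec("point", {"value": 1.0})
        elif isinstance(ratio, (int, float)):
            rspec = DistributionSpec("point", {"value": float(ratio)})
        else:
            rspec = DistributionSpec.from_dict(ratio)
        dc = entry.get("dc", base.dc if base else {"male": 0.0, "female": 0.0})
        inv[name] = NuclideRecord(
            name=name,
            decay_const=lam,
            ratio_spec=rspec,
            dc=dict(dc),
            parent=entry.get("parent", base.parent if base else None),
            fixed_ratio=base.fixed_ratio if base else False,
        )
    return inv
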