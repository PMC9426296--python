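"""Parametric uncertainty distributions and reproducible sampling.

Every uncertain model parameter is described by a :class:`DistributionSpec`
from one of five families: point (degenerate), U (uniform), TR (triangular),
TN (truncated normal) and TLN (truncated lognormal).  Sampling is by
inverse-CDF on the truncated quantile range, so (a) every realization
consumes exactly one uniform variate per parameter — substream bookkeeping
is deterministic — and (b) correlated parameters can be coupled through a
Gaussian copula with a stated Pearson-like coefficient and then mapped to
their marginals.

Lognormal conventions: a TLN spec is parameterised by the geometric mean
(GM) and geometric standard deviation (GSD); the arithmetic mean of the
untruncated lognormal is AM = GM * exp((ln GSD)^2 / 2).  ``gm_from_am_gsd``
inverts this; a printed-form variant without the 1/2 factor is available
behind a flag for comparison with legacy parameter tables.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DistributionSpec",
    "RngStream",
    "point",
    "uniform",
    "triangular",
    "truncnorm",
    "trunclognorm",
    "gm_from_am_gsd",
    "am_from_gm_gsd",
    "empirical_gsd",
    "sample_correlated",
]

_FAMILIES = ("point", "U", "TR", "TN", "TLN")


@dataclass(frozen=True)
class DistributionSpec:
    """Tagged parametric distribution with truncation bounds.

    params by family:
      point: value
      U:     min, max
      TR:    min, mode, max
      TN:    am, sd, min, max
      TLN:   gm, gsd, min, max
    """

    family: str
    params: Mapping[str, float]
    corr_group: Optional[str] = None
    r: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        p = self.params
        if self.family == "U":
            if p["min"] > p["max"]:
                raise ValueError("uniform: min > max")
        elif self.family == "TR":
            if not (p["min"] <= p["mode"] <= p["max"]):
                raise ValueError("triangular: need min <= mode <= max")
        elif self.family == "TN":
            if p["sd"] < 0:
                raise ValueError("truncated normal: sd < 0")
            if p["min"] > p["max"]:
                raise ValueError("truncated normal: min > max")
        elif self.family == "TLN":
            if p["gm"] <= 0 or p["gsd"] < 1:
                raise ValueError("truncated lognormal: need gm > 0, gsd >= 1")
            if p["min"] > p["max"] or p["max"] <= 0:
                raise ValueError("truncated lognormal: bad bounds")
        if self.r is not None and abs(self.r) > 1:
            raise ValueError(f"|r| must be <= 1, got {self.r}")

    # -- central values -------------------------------------------------

    def central(self) -> float:
        """Arithmetic-mean-consistent central value of the (untruncated) family."""
        p = self.params
        if self.family == "point":
            return p["value"]
        if self.family == "U":
            return 0.5 * (p["min"] + p["max"])
        if self.family == "TR":
            return (p["min"] + p["mode"] + p["max"]) / 3.0
        if self.family == "TN":
            return p["am"]
        return am_from_gm_gsd(p["gm"], p["gsd"])

    @property
    def is_degenerate(self) -> bool:
        p = self.params
        if self.family == "point":
            return True
        if self.family in ("U", "TR"):
            return p["min"] == p["max"]
        if self.family == "TN":
            return p["sd"] == 0 or p["min"] == p["max"]
        return p["gsd"] == 1 or p["min"] == p["max"]

    # -- inverse CDF on the truncated range ------------------------------

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function restricted to [min, max]; *u* in [0, 1]."""
        u = np.asarray(u, dtype=float)
        p = self.params
        if self.family == "point":
            return np.full_like(u, p["value"])
        if self.family == "U":
            return p["min"] + u * (p["max"] - p["min"])
        if self.family == "TR":
            lo, m, hi = p["min"], p["mode"], p["max"]
            if hi == lo:
                return np.full_like(u, lo)
            c = (m - lo) / (hi - lo)
            return stats.triang.ppf(u, c, loc=lo, scale=hi - lo)
        if self.family == "TN":
            am, sd, lo, hi = p["am"], p["sd"], p["min"], p["max"]
            if sd == 0:
                return np.full_like(u, min(max(am, lo), hi))
            a, b = (lo - am) / sd, (hi - am) / sd
            if not stats.norm.cdf(b) > stats.norm.cdf(a):
                raise ValueError("truncated normal: zero probability mass in bounds")
            return stats.truncnorm.ppf(u, a, b, loc=am, scale=sd)
        # TLN: truncate in log space, invert through the normal quantile
        gm, gsd, lo, hi = p["gm"], p["gsd"], p["min"], p["max"]
        if gsd == 1:
            return np.full_like(u, min(max(gm, lo), hi))
        mu, sigma = math.log(gm), math.log(gsd)
        a = stats.norm.cdf((math.log(lo) - mu) / sigma) if lo > 0 else 0.0
        b = stats.norm.cdf((math.log(hi) - mu) / sigma)
        if not b > a:
            raise ValueError("truncated lognormal: zero probability mass in bounds")
        return np.exp(mu + sigma * stats.norm.ppf(a + u * (b - a)))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n inverse-CDF draws using exactly n uniforms from *rng*."""
        return self.ppf(rng.random(n))

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"family": self.family, "params": dict(self.params)}
        if self.corr_group is not None:
            d["corr_group"] = self.corr_group
        if self.r is not None:
            d["r"] = self.r
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        return cls(
            family=d["family"],
            params=dict(d["params"]),
            corr_group=d.get("corr_group"),
            r=d.get("r"),
        )


# -- convenience constructors ------------------------------------------------

def point(value: float, **kw) -> DistributionSpec:
    return DistributionSpec("point", {"value": value}, **kw)


def uniform(lo: float, hi: float, **kw) -> DistributionSpec:
    return DistributionSpec("U", {"min": lo, "max": hi}, **kw)


def triangular(lo: float, mode: float, hi: float, **kw) -> DistributionSpec:
    return DistributionSpec("TR", {"min": lo, "mode": mode, "max": hi}, **kw)


def truncnorm(am: float, sd: float, lo: float, hi: float, **kw) -> DistributionSpec:
    return DistributionSpec("TN", {"am": am, "sd": sd, "min": lo, "max": hi}, **kw)


def trunclognorm(gm: float, gsd: float, lo: float, hi: float, **kw) -> DistributionSpec:
    return DistributionSpec("TLN", {"gm": gm, "gsd": gsd, "min": lo, "max": hi}, **kw)


# -- lognormal moment conversions --------------------------------------------

def gm_from_am_gsd(am: float, gsd: float, printed_form: bool = False) -> float:
    """Geometric mean of a lognormal with arithmetic mean *am* and GSD *gsd*.

    Default uses the standard relation GM = AM * exp(-(ln GSD)^2 / 2).  With
    ``printed_form=True`` the factor 1/2 is dropped (GM = AM * exp(-(ln GSD)^2)),
    matching a form found in some legacy parameter tables.
    """
    if am <= 0:
        raise ValueError("arithmetic mean must be positive")
    if gsd < 1:
        raise ValueError("GSD must be >= 1")
    s2 = math.log(gsd) ** 2
    return am * math.exp(-s2 if printed_form else -0.5 * s2)


def am_from_gm_gsd(gm: float, gsd: float) -> float:
    """Arithmetic mean of an (untruncated) lognormal with given GM and GSD."""
    return gm * math.exp(0.5 * math.log(gsd) ** 2)


def empirical_gsd(values: Sequence[float]) -> float:
    """exp of the (population) standard deviation of the log values.

    Requires at least two strictly positive values; zero doses must be
    excluded upstream (a structurally unexposed pathway has no GSD).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if np.any(v <= 0):
        raise ValueError("all values must be positive")
    return float(np.exp(np.std(np.log(v), ddof=0)))


# -- correlated sampling ------------------------------------------------------

def sample_correlated(
    specs: Sequence[DistributionSpec],
    rng: np.random.Generator,
    n: int = 1,
) -> np.ndarray:
    """Sample a correlation group through a Gaussian copula.

    The first spec is the group anchor; every other spec carries a
    coefficient ``r`` against the anchor.  Marginals are honoured exactly
    (inverse-CDF transform); the copula correlation is the stated ``r``.
    Returns an array of shape ``(len(specs), n)``.
    """
    k = len(specs)
    out = np.empty((k, n))
    z0 = rng.standard_normal(n)
    out[0] = specs[0].ppf(stats.norm.cdf(z0))
    for i, spec in enumerate(specs[1:], start=1):
        r = 1.0 if spec.r is None else spec.r
        if abs(r) > 1:
            raise ValueError(f"|r| must be <= 1, got {r}")
        if r == 1.0:
            z = z0
        elif r == -1.0:
            z = -z0
        else:
            z = r * z0 + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
        out[i] = spec.ppf(stats.norm.cdf(z))
    return out


# -- hierarchical reproducible streams ----------------------------------------

def _key_ints(key: Sequence) -> list[int]:
    out = []
    for part in key:
        h = hashlib.sha256(repr(part).encode()).digest()
        out.append(int.from_bytes(h[:4], "big"))
    return out


@dataclass(frozen=True)
class RngStream:
    """Hierarchical reproducible random streams.

    ``stream(*key)`` derives an independent ``numpy`` generator from the
    master seed and a tuple key (subject id, parameter id, ...).  The same
    (seed, key) always yields the identical draw sequence; distinct keys
    yield independent streams.
    """

    seed: int

    def stream(self, *key) -> np.random.Generator:
        ss = np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, *_key_ints(key)])
        return np.random.default_rng(ss)

    def child(self, *key) -> "RngStream":
        """A derived stream factory whose keys are all prefixed by *key*."""
        ss = np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, *_key_ints(key)])
        return RngStream(seed=int(ss.generate_state(1)[0]) & 0x7FFFFFFF)
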