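"""Reporting surfaces: dose-interval tables, window cross-tabulations,
GSD distributions and dose/birth-year correlations.

These mirror the standard presentation of reconstructed-dose cohorts:
children binned by parental pathway dose (left-closed mGy intervals),
a cross-tabulation of the DOB-51 and DOB-38 window doses (with common
random numbers all mass lies on or above the diagonal), the distribution
of per-subject geometric standard deviations over nonzero-dose subjects,
and Pearson correlations between dose (linear or log) and the child's
year of birth.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DOSE_BIN_LABELS, dose_bin_index

#: GSD-interval bins, left-closed, partitioning [1, inf).
GSD_BIN_EDGES = (1.0, 1.3, 1.5, 2.0, 2.5, 3.0, 3.5)
GSD_BIN_LABELS = ("<1.3", "1.3-1.49", "1.5-1.99", "2-2.49", "2.5-2.99", "3-3.49", "3.5+")


def _round_half_up(x: float, digits: int = 1) -> float:
    scale = 10 ** digits
    return math.floor(x * scale + 0.5) / scale


def gsd_bin_index(gsd: float) -> int:
    if gsd < 1.0:
        raise ValueError("GSD cannot be below 1")
    for i, hi in enumerate(GSD_BIN_EDGES[1:]):
        if gsd < hi:
            return i
    return len(GSD_BIN_LABELS) - 1


def pathway_summary(
    doses: Mapping[str, float],
    include_zero: bool = True,
) -> pd.DataFrame:
    """Dose-interval table: per-bin n, percent and arithmetic mean dose.

    *doses* maps subject/child id to a central dose (mGy).  With
    ``include_zero=False``, zero-dose entries (structurally unexposed) are
    dropped before binning — the exposed-only subsetting used for the
    pathway-specific columns.  The final "entire" row recomputes over the
    ungrouped data.
    """
    items = [(k, v) for k, v in doses.items() if include_zero or v > 0]
    n_total = len(items)
    rows = []
    for i, label in enumerate(DOSE_BIN_LABELS):
        members = [v for _, v in items if dose_bin_index(v) == i]
        rows.append(
            {
                "bin": label,
                "n": len(members),
                "percent": _round_half_up(100.0 * len(members) / n_total, 1)
                if n_total
                else 0.0,
                "mean_mgy": float(np.mean(members)) if members else float("nan"),
            }
        )
    all_values = [v for _, v in items]
    rows.append(
        {
            "bin": "entire",
            "n": n_total,
            "percent": 100.0 if n_total else 0.0,
            "mean_mgy": float(np.mean(all_values)) if all_values else float("nan"),
        }
    )
    return pd.DataFrame(rows)


def crosstab_windows(
    doses_51: Mapping[str, float], doses_38: Mapping[str, float]
) -> np.ndarray:
    """7x7 count matrix of (DOB-51 bin, DOB-38 bin) pairs, paired by child."""
    if set(doses_51) != set(doses_38):
        missing = set(doses_51) ^ set(doses_38)
        raise ValueError(f"unpaired children in cross-tabulation: {sorted(missing)}")
    k = len(DOSE_BIN_LABELS)
    mat = np.zeros((k, k), dtype=int)
    for child, d51 in doses_51.items():
        mat[dose_bin_index(d51), dose_bin_index(doses_38[child])] += 1
    return mat


def gsd_table(
    gsds: Mapping[str, float], doses: Mapping[str, float]
) -> pd.DataFrame:
    """GSD-interval table over nonzero-dose subjects: n, percent, mean dose."""
    items = [(k, gsds[k], doses[k]) for k in gsds]
    n_total = len(items)
    rows = []
    for i, label in enumerate(GSD_BIN_LABELS):
        members = [(g, d) for _, g, d in items if gsd_bin_index(g) == i]
        rows.append(
            {
                "bin": label,
                "n": len(members),
                "percent": _round_half_up(100.0 * len(members) / n_total, 1)
                if n_total
                else 0.0,
                "mean_dose_mgy": float(np.mean([d for _, d in members]))
                if members
                else float("nan"),
            }
        )
    rows.append(
        {
            "bin": "entire",
            "n": n_total,
            "percent": 100.0 if n_total else 0.0,
            "mean_dose_mgy": float(np.mean([d for _, _, d in items]))
            if items
            else float("nan"),
        }
    )
    return pd.DataFrame(rows)


def dose_birthyear_correlation(
    doses: Sequence[float],
    birth_years: Sequence[int],
    scale: str = "linear",
) -> tuple[float, float]:
    """Pearson r and two-sided p between (log-)dose and year of birth.

    On the log scale, zero doses are excluded (with their paired years).
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(birth_years, dtype=float)
    if d.size != y.size:
        raise ValueError("doses and birth years must pair one-to-one")
    if scale == "log":
        mask = d > 0
        d, y = np.log(d[mask]), y[mask]
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    if d.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(d) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance")
    r, p = stats.pearsonr(d, y)
    return float(r), float(p)


def render_table(df: pd.DataFrame, title: str = "") -> str:
    """Aligned-text rendering of a summary table."""
    body = df.to_string(index=False, float_format=lambda v: f"{v:.3g}")
    return (title + "\n" + body) if title else body
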