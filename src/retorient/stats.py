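"""Descriptive sectoral statistics and group-comparison tests.

Per-sector metrics from many subjects are summarized Table-style (mean,
SD, min, max, n per sector and metric) and compared between cohorts with
the non-parametric Mann–Whitney U test; associations between metrics use
Pearson correlation.

Preferred orientation is axial data (θ and θ+180° are the same line), so
arithmetic summaries near the 0°/180° wrap are misleading: {10°, 170°}
averages to 90° arithmetically but the two lines are only 20° apart and
their axial mean is 0°. Both summaries are emitted, clearly labeled; the
axial circular mean uses angle doubling:

    mean_axial = ½·atan2(Σ sin 2θ, Σ cos 2θ), folded into [0°, 180°).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .image import fold_axial

__all__ = [
    "axial_mean",
    "axial_std",
    "describe",
    "sector_descriptives",
    "mann_whitney_u",
    "pearson_r",
]

# exact enumeration is used when both groups are small enough for it to be
# cheap; beyond this the tie-corrected normal approximation takes over
_EXACT_MIN_N = 8
_EXACT_TOTAL_N = 25


def axial_mean(theta_deg) -> float:
    """Axial circular mean of angles in degrees, folded into [0°, 180°).

    Invariant to adding 180° to any subset of the observations.
    """
    t = np.radians(2.0 * np.asarray(theta_deg, dtype=float))
    if t.size == 0:
        raise ValueError("axial mean of an empty sample")
    return float(fold_axial(0.5 * np.degrees(np.arctan2(np.sin(t).sum(), np.cos(t).sum()))))


def axial_std(theta_deg) -> float:
    """Axial circular standard deviation (degrees) via angle doubling.

    Half the circular SD sqrt(−2 ln R̄) of the doubled angles; 0 for a
    perfectly aligned sample, growing without bound as the sample
    approaches isotropy.
    """
    t = np.radians(2.0 * np.asarray(theta_deg, dtype=float))
    if t.size == 0:
        raise ValueError("axial SD of an empty sample")
    rbar = float(np.hypot(np.sin(t).mean(), np.cos(t).mean()))
    if rbar <= 0:
        return float("inf")
    rbar = min(rbar, 1.0)
    return float(0.5 * np.degrees(np.sqrt(-2.0 * np.log(rbar))))


def describe(values, circular: bool = False) -> dict[str, float]:
    """Mean, SD (ddof=1), min, max and n of one cell; optionally axial stats."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot describe an empty sample")
    out = {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
        "n": int(v.size),
    }
    if circular:
        out["axial_mean"] = axial_mean(v)
        out["axial_sd"] = axial_std(v)
    return out


def sector_descriptives(table: pd.DataFrame, value_col: str = "value",
                        metric_col: str = "metric",
                        sector_col: str = "sector") -> pd.DataFrame:
    """Summarize a long-format table into per-(metric, sector) rows.

    ``table`` holds one row per subject × sector × metric. Orientation
    metrics (any metric name containing "orientation") additionally get the
    axial circular mean/SD columns.
    """
    required = {value_col, metric_col, sector_col}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    rows = []
    for (metric, sector), grp in table.groupby([metric_col, sector_col], sort=False):
        circular = "orientation" in str(metric).lower()
        d = describe(grp[value_col].to_numpy(), circular=circular)
        rows.append({"metric": metric, "sector": sector, **d})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str


def mann_whitney_u(group_a, group_b, alternative: str = "two-sided") -> MannWhitneyResult:
    """Mann–Whitney U test (Wilcoxon rank-sum) between two samples.

    Returns the U statistic of ``group_a`` (midranks for ties). The
    p-value is computed by exact enumeration of all group labelings when
    min(n) ≤ 8 and n_a + n_b ≤ 25, and by the tie-corrected normal
    approximation (with continuity correction) otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if min(a.size, b.size) <= _EXACT_MIN_N and a.size + b.size <= _EXACT_TOTAL_N:
        # full enumeration of all C(n_a+n_b, n_a) labelings (handles ties)
        method = sps.PermutationMethod(n_resamples=2_000_000, batch=20_000)
        res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
        label = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
        label = "asymptotic"
    return MannWhitneyResult(u=float(res.statistic), p_value=float(res.pvalue), method=label)


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p_value: float
    n: int


def pearson_r(x, y) -> PearsonResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    res = sps.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p_value=float(res.pvalue), n=int(x.size))
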