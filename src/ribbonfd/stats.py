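"""Group statistics: Mann-Whitney U comparisons and Pearson correlations.

The study design is a two-group (adolescent vs adult) cross-sectional
comparison run separately per sex, with a Mann-Whitney U test per region
and measure, plus Pearson correlations between fractal dimension and
grey-matter volume pooled across groups within each sex.

Conventions, chosen to match standard SPSS-style output:

* U is ``min(U1, U2)``, so 0 <= U <= n1*n2 and complete overlap gives
  U = n1*n2/2.
* The two-tailed p is exact — full enumeration of all C(n1+n2, n1)
  group assignments — whenever n1+n2 <= 16 and the pooled sample is
  tie-free; otherwise the normal approximation with tie correction and
  continuity correction is used.
* Group summaries report sample standard deviations (n-1 denominator).
* Raw per-region p-values are reported as in the original design;
  Holm-adjusted p-values are emitted alongside as a clearly-labeled
  extension, never replacing the raw ones.

A cohort is a tidy :class:`pandas.DataFrame` with one row per (subject,
region) and columns ``subject_id, group, sex, region`` plus measure
columns (``fd_bc, fd_mb, volume_mm3, surface_mm2``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GROUPS",
    "SEXES",
    "MEASURES",
    "GroupComparison",
    "CorrelationResult",
    "mann_whitney_u",
    "pearson_r",
    "compare_groups",
    "fd_volume_correlations",
    "holm_adjust",
]

GROUPS = ("adolescent", "adult")
SEXES = ("female", "male")
MEASURES = ("fd_bc", "fd_mb", "volume_mm3", "surface_mm2")

#: exact enumeration is used up to this pooled sample size (tie-free data)
EXACT_LIMIT = 16


@dataclass(frozen=True)
class GroupComparison:
    region: str
    measure_name: str
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    U: float
    p: float
    direction: str  # which group has the larger mean


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    n: int
    R: float
    p: float


def _as_array(sample: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"sample {name!r} must be a non-empty 1D sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name!r} contains non-finite values")
    return arr


def _exact_two_tailed_p(u_obs: float, n1: int, n2: int) -> float:
    """P(min(U1, U2) <= u_obs) under full enumeration of rank assignments.

    With no ties the pooled ranks are exactly 1..N, so enumerating which
    ranks go to the first sample enumerates all C(N, n1) assignments.
    """
    n = n1 + n2
    base = n1 * (n1 + 1) // 2
    total = math.comb(n, n1)
    hits = 0
    for ranks in combinations(range(1, n + 1), n1):
        u1 = sum(ranks) - base
        if min(u1, n1 * n2 - u1) <= u_obs + 1e-9:
            hits += 1
    return hits / total


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Mann-Whitney test; returns (U, two-tailed p).

    U follows the ``min(U1, U2)`` convention.  See the module docstring
    for when the exact enumeration vs the corrected normal approximation
    is used.  When every pooled value is tied, U = n1*n2/2 and p = 1.
    """
    a = _as_array(a, "a")
    b = _as_array(b, "b")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks under ties
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u = min(u1, n1 * n2 - u1)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if not has_ties and n1 + n2 <= EXACT_LIMIT:
        return u, _exact_two_tailed_p(u, n1, n2)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # every pooled value identical
        return u, 1.0
    z = max(abs(u - mu) - 0.5, 0.0) / math.sqrt(var)  # continuity correction
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return u, p


def pearson_r(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationResult:
    """Pearson product-moment correlation with a two-tailed t-based p-value."""
    x = _as_array(x, x_name)
    y = _as_array(y, y_name)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError(f"need n >= 3 pairs, got {len(x)}")
    for arr, name in ((x, x_name), (y, y_name)):
        if np.ptp(arr) == 0:
            raise ValueError(f"variable {name!r} has zero variance")
    res = sps.pearsonr(x, y)
    return CorrelationResult(
        x_name=x_name, y_name=y_name, n=len(x),
        R=float(res.statistic), p=float(res.pvalue),
    )


def _require_columns(cohort: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns {missing}")


def compare_groups(
    cohort: pd.DataFrame,
    sex: str,
    region: str,
    measure_name: str,
) -> GroupComparison:
    """Adolescent-vs-adult comparison for one sex, region and measure."""
    _require_columns(cohort, ["group", "sex", "region", measure_name])
    sub = cohort[(cohort["sex"] == sex) & (cohort["region"] == region)]
    samples = {}
    for group in GROUPS:
        vals = sub.loc[sub["group"] == group, measure_name].dropna().to_numpy(float)
        if vals.size == 0:
            raise ValueError(f"no {group!r} subjects of sex {sex!r} in region {region!r}")
        samples[group] = vals
    a, b = samples["adolescent"], samples["adult"]
    u, p = mann_whitney_u(a, b)
    mean1, mean2 = float(a.mean()), float(b.mean())
    return GroupComparison(
        region=region,
        measure_name=measure_name,
        n1=len(a),
        n2=len(b),
        mean1=mean1,
        sd1=float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        mean2=mean2,
        sd2=float(b.std(ddof=1)) if len(b) > 1 else 0.0,
        U=u,
        p=p,
        direction="adolescent" if mean1 >= mean2 else "adult",
    )


def fd_volume_correlations(
    cohort: pd.DataFrame,
    sex: str,
    fd_measure: str = "fd_bc",
    regions: Sequence[str] = ("LH", "RH", "WB"),
) -> list[CorrelationResult]:
    """FD-vs-volume Pearson correlations, pooled across groups within a sex.

    One correlation per region, pairing that region's grey-matter volume
    with its fractal dimension (the hemisphere/whole-brain pairings of
    the standard report).  Regions absent from the table are skipped.
    """
    _require_columns(cohort, ["sex", "region", "volume_mm3", fd_measure])
    out: list[CorrelationResult] = []
    for region in regions:
        sub = cohort[(cohort["sex"] == sex) & (cohort["region"] == region)]
        sub = sub.dropna(subset=["volume_mm3", fd_measure])
        if len(sub) < 3:
            continue
        out.append(
            pearson_r(
                sub["volume_mm3"].to_numpy(float),
                sub[fd_measure].to_numpy(float),
                x_name=f"GM-{region}",
                y_name=f"FD-{region}",
            )
        )
    return out


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]
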