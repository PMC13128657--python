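"""Nonparametric comparison machinery for settlement indicators.

Cost, stay and differential distributions in claims data are heavily
right-skewed, so groups are summarised as median (P25, P75) and compared
with rank tests: Mann-Whitney U for two groups, Kruskal-Wallis for several,
and the chi-square test for categorical contrasts.  Effect sizes are
Hodges-Lehmann median differences — the median of all between-group pairwise
differences — with the distribution-free Moses confidence interval whose cut
point comes from the Mann-Whitney null quantile.

Conventions (fixed and reported in output metadata): exact Mann-Whitney
p-values by enumeration when both samples have at most 20 observations and
there are no ties, otherwise the tie-corrected normal approximation without
continuity correction (so the two-group Kruskal-Wallis identity H = Z**2
holds); quartiles by linear interpolation between closest ranks; the Moses
interval uses the normal-quantile cut without interpolation between order
statistics (conservative for tiny samples); two-sided alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "MannWhitneyResult",
    "HodgesLehmannResult",
    "GroupSummary",
    "GroupComparison",
    "mann_whitney",
    "kruskal_wallis",
    "chi_square",
    "hodges_lehmann",
    "compare_groups",
]

EXACT_THRESHOLD = 20  # exact enumeration when min(n_x, n_y) <= 20 and no ties


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    z: float  # tie-corrected normal deviate (no continuity correction)
    p_value: float
    method: str  # "exact" | "asymptotic"


@dataclass(frozen=True)
class HodgesLehmannResult:
    md: float
    ci_low: float
    ci_high: float
    level: float


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    p25: float
    p75: float


@dataclass(frozen=True)
class GroupComparison:
    indicator: str
    case_summary: GroupSummary
    control_summary: GroupSummary
    u_statistic: float
    z_statistic: float
    md: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.md <= self.ci_high):
            raise DomainError("Hodges-Lehmann CI must bracket the point estimate")


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise DomainError(f"sample {name!r} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"sample {name!r} contains non-finite values")
    return arr


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; case sample first.

    Exact enumeration for small tie-free samples, else the tie-corrected
    normal approximation.  The reported Z is always the normal deviate
    ``(U - mu) / sigma`` (useful alongside the asymptotic p and identical in
    sign convention to SPSS output up to orientation).
    """
    xa, ya = _as_sample(x, "x"), _as_sample(y, "y")
    nx, ny = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = stats.rankdata(pooled)
    u_x = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    n = nx + ny
    mu = nx * ny / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    z = 0.0 if var <= 0 else (u_x - mu) / np.sqrt(var)
    if min(nx, ny) <= EXACT_THRESHOLD and not has_ties:
        res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method="exact")
        return MannWhitneyResult(u=float(u_x), z=float(z), p_value=float(res.pvalue), method="exact")
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return MannWhitneyResult(u=float(u_x), z=float(z), p_value=float(p), method="asymptotic")


def kruskal_wallis(groups: Sequence) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square (k-1 df) p-value."""
    if len(groups) < 2:
        raise DomainError("kruskal_wallis requires at least two groups")
    arrays = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):  # identical values: no evidence, H = 0
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square without continuity correction; df = (r-1)(k-1)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise DomainError("contingency table must be 2-dimensional")
    if np.any(t < 0):
        raise DomainError("counts must be non-negative")
    if t.sum() <= 0:
        raise DomainError("contingency table total must be > 0")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DomainError("contingency table has a zero marginal")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def hodges_lehmann(x, y, level: float = 0.95) -> HodgesLehmannResult:
    """Hodges-Lehmann shift estimate x - y with the Moses rank-based CI.

    The point estimate is the median of all ``n_x * n_y`` pairwise
    differences; the interval takes the order statistics at cut
    ``K = floor(N/2 - z * sqrt(n_x n_y (n_x + n_y + 1) / 12))`` from each end
    (clamped to the extremes, which is conservative for tiny samples).
    """
    xa, ya = _as_sample(x, "x"), _as_sample(y, "y")
    if not (0.0 < level < 1.0):
        raise DomainError(f"confidence level must lie in (0, 1), got {level}")
    diffs = np.subtract.outer(xa, ya).ravel()
    diffs.sort()
    md = float(np.median(diffs))
    n_big = diffs.size
    z = stats.norm.ppf(0.5 + level / 2.0)
    sigma = np.sqrt(xa.size * ya.size * (xa.size + ya.size + 1) / 12.0)
    k = int(np.floor(n_big / 2.0 - z * sigma))
    k = max(k, 0)
    return HodgesLehmannResult(
        md=md, ci_low=float(diffs[k]), ci_high=float(diffs[n_big - 1 - k]), level=level
    )


def compare_groups(cases, controls, indicator: str, level: float = 0.95) -> GroupComparison:
    """Case-vs-control comparison of one settlement indicator.

    Sign convention: case minus control, so a DIP-differential median
    difference is negative when infected patients lose more.
    """
    xa, ya = _as_sample(cases, "cases"), _as_sample(controls, "controls")
    mw = mann_whitney(xa, ya)
    hl = hodges_lehmann(xa, ya, level=level)

    def summarise(a: np.ndarray) -> GroupSummary:
        p25, med, p75 = np.percentile(a, [25, 50, 75])  # linear interpolation
        return GroupSummary(n=a.size, median=float(med), p25=float(p25), p75=float(p75))

    return GroupComparison(
        indicator=indicator,
        case_summary=summarise(xa),
        control_summary=summarise(ya),
        u_statistic=mw.u,
        z_statistic=mw.z,
        md=hl.md,
        ci_low=hl.ci_low,
        ci_high=hl.ci_high,
        p_value=mw.p_value,
        method=mw.method,
    )
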