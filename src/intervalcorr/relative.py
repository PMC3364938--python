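"""Relative-distance test.

Each query point q is located within the gap between its two flanking
reference points (k_left <= q < k_right); the raw ratio
r = (q - k_left) / (k_right - k_left) is folded to d = min(r, 1 - r), so
d lies in [0, 1/2]. If the query is placed independently of the reference,
the d values are uniform on [0, 1/2]. Departures from uniformity toward 0
indicate attraction (query points hug reference points), toward 1/2
indicate avoidance (query points sit mid-gap).

Three summaries of the d sample are provided:

* a one-sample Kolmogorov–Smirnov test against the uniform null;
* the signed area S between the empirical CDF of d and the null CDF
  (the straight line y = 2x on [0, 1/2]), with a permutation p-value
  obtained by redrawing samples from the uniform null;
* the correlation-like measure 4*S = 1 - 4*mean(d), which is +1 when every
  query point coincides with a reference point, -1 when every query point
  falls mid-gap, and 0 in expectation under independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import SkipScope

__all__ = [
    "RelativeDistanceResult",
    "relative_distances",
    "ks_uniform_test",
    "ecdf_area",
    "area_permutation_test",
    "correlation_measure",
    "relative_distance_test",
]


@dataclass
class RelativeDistanceResult:
    n_query: int
    ks_statistic: float
    ks_p: float
    area_S: float
    area_p: float
    correlation: float
    direction: str  # "closer" | "farther" | "none"
    n_dropped: int = 0

    statistic_name = "correlation"

    @property
    def statistic(self) -> float:
        return self.correlation

    @property
    def p(self) -> float:
        return min(self.ks_p, self.area_p)


def relative_distances(
    query: np.ndarray,
    reference: np.ndarray,
    chrom_length: int,
    edge_mode: str = "circular",
) -> np.ndarray:
    """Folded relative distances d in [0, 1/2] of query points to reference gaps.

    ``query`` and ``reference`` are 1-D integer position arrays on one
    chromosome of length ``chrom_length``. Reference positions are
    deduplicated (repeated reference points would create zero-width gaps).

    edge_mode="circular" (default) closes the chromosome into a ring, so the
    gap from the last reference wraps around to the first and every query
    point has flanking references; a single reference point suffices.
    edge_mode="drop" keeps the chromosome linear and silently excludes query
    points outside [first_ref, last_ref); at least two distinct references
    are then required. The number dropped is ``len(query) - len(result)``.
    """
    query = np.asarray(query)
    refs = np.unique(np.asarray(reference))
    L = int(chrom_length)
    if len(query) == 0:
        raise SkipScope("no query points on chromosome")
    if edge_mode not in ("circular", "drop"):
        raise ValueError(f"unknown edge_mode: {edge_mode!r}")
    n = len(refs)
    if edge_mode == "circular":
        if n < 1:
            raise SkipScope("no reference points on chromosome")
        idx = np.searchsorted(refs, query, side="right")
        left = refs[(idx - 1) % n]
        right = refs[idx % n]
        gap = np.mod(right - left, L).astype(np.float64)
        gap[gap == 0] = L  # single reference: the whole ring is one gap
        offset = np.mod(query - left, L)
    else:
        if n < 2:
            raise SkipScope("fewer than 2 distinct reference points on chromosome")
        keep = (query >= refs[0]) & (query < refs[-1])
        query = query[keep]
        if len(query) == 0:
            raise SkipScope("no query points between outermost references")
        idx = np.searchsorted(refs, query, side="right")
        left = refs[idx - 1]
        right = refs[idx]
        gap = (right - left).astype(np.float64)
        offset = query - left
    r = offset / gap
    return np.minimum(r, 1.0 - r)


def _check_range(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=np.float64)
    if d.size == 0:
        raise SkipScope("empty relative-distance sample")
    if (d < 0).any() or (d > 0.5).any():
        raise ValueError("relative distances must lie in [0, 1/2]")
    return d


def ks_uniform_test(d) -> tuple[float, float]:
    """One-sample KS test of 2*d against Uniform(0, 1); asymptotic two-sided p."""
    d = _check_range(d)
    res = stats.kstest(2.0 * d, "uniform", method="asymp")
    return float(res.statistic), float(res.pvalue)


def ecdf_area(d) -> float:
    """Signed area S = integral over [0, 1/2] of (ECDF(x) - 2x) dx.

    Computed exactly from the sorted sample: the ECDF is piecewise constant
    with jumps of 1/n at each d value, and the null CDF is the line 2x.
    Positive S means mass shifted toward 0 (attraction), negative toward 1/2.
    """
    d = np.sort(_check_range(d))
    n = len(d)
    x = np.concatenate(([0.0], d, [0.5]))
    heights = np.arange(n + 1) / n  # ECDF value on [x_i, x_{i+1})
    integral_ecdf = float(np.sum(heights * np.diff(x)))
    return integral_ecdf - 0.25  # integral of 2x over [0, 1/2] is 1/4


def area_permutation_test(
    S_obs: float, n_query: int, n_perm: int, rng
) -> float:
    """Permutation p-value for the ECDF-area statistic S.

    Draws ``n_query`` values from the uniform null on [0, 1/2] ``n_perm``
    times and compares |S| of each draw to |S_obs|; two-sided with the
    add-one correction p = (1 + #{|S_perm| >= |S_obs|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng)
    draws = rng.uniform(0.0, 0.5, size=(n_perm, n_query))
    # for a sample, S = 1/4 - mean(d) exactly (see ecdf_area)
    S_perm = 0.25 - draws.mean(axis=1)
    exceed = int(np.count_nonzero(np.abs(S_perm) >= abs(S_obs)))
    return (1 + exceed) / (n_perm + 1)


def correlation_measure(d) -> float:
    """Rescaled area 4*S = 1 - 4*mean(d), in [-1, 1]."""
    return 4.0 * ecdf_area(d)


def relative_distance_test(
    d, n_perm: int, rng, alpha: float = 0.05, n_dropped: int = 0
) -> RelativeDistanceResult:
    """Run all relative-distance summaries on a (possibly pooled) d sample."""
    d = _check_range(d)
    ks_stat, ks_p = ks_uniform_test(d)
    S = ecdf_area(d)
    area_p = area_permutation_test(S, len(d), n_perm, rng)
    corr = 4.0 * S
    if min(ks_p, area_p) < alpha and corr > 0:
        direction = "closer"
    elif min(ks_p, area_p) < alpha and corr < 0:
        direction = "farther"
    else:
        direction = "none"
    return RelativeDistanceResult(
        n_query=len(d),
        ks_statistic=ks_stat,
        ks_p=ks_p,
        area_S=S,
        area_p=area_p,
        correlation=corr,
        direction=direction,
        n_dropped=n_dropped,
    )
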