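"""Overlap tests: the projection (binomial) test and the Jaccard test.

The projection test asks whether query points fall inside reference
intervals more or less often than chance. Under independence the
probability that one query point lands in a reference interval equals the
fraction of the chromosome covered by the (merged) reference, so the hit
count K out of n query points is Binomial(n, coverage); significance comes
from the exact two-sided binomial test. The test carries little information
when the reference covers almost none or almost all of the chromosome, and
the result is flagged accordingly.

The Jaccard test compares two interval sets symmetrically through
J = |Q ∩ R| / |Q ∪ R| in base pairs. Its null distribution is obtained by
spacing-preserving randomization of the query: by default each permutation
applies an independent uniform circular rotation of the whole query set on
each chromosome (interval lengths and all inter-interval gaps preserved
exactly; intervals wrapping the origin are split); a gap-shuffle mode that
permutes the inter-interval gaps before applying a random phase is also
provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import SkipScope
from .genome import FeatureSet, GenomeSpace, PointSet, _merge

__all__ = [
    "ProjectionResult",
    "JaccardResult",
    "projection_test",
    "jaccard_statistic",
    "jaccard_permutation_test",
    "jaccard_test",
    "rotate_intervals",
]


@dataclass
class ProjectionResult:
    n_query: int
    n_hits: int
    coverage_p: float
    p: float
    direction: str  # "overlapping" | "nonoverlapping" | "none"
    low_information: bool = False

    statistic_name = "n_hits"

    @property
    def statistic(self) -> float:
        return self.n_hits


@dataclass
class JaccardResult:
    jaccard: float
    p: float
    direction: str  # "overlapping" | "nonoverlapping" | "none"
    n_perm: int

    statistic_name = "jaccard"

    @property
    def statistic(self) -> float:
        return self.jaccard


def _scope_chroms(space: GenomeSpace, scope: str | None) -> list[str]:
    if scope is None or scope == "genome":
        return space.names
    if scope not in space:
        raise KeyError(f"unknown chromosome: {scope!r}")
    return [scope]


def _count_hits(points: np.ndarray, intervals: np.ndarray) -> int:
    """Number of points inside half-open merged intervals."""
    if len(points) == 0 or len(intervals) == 0:
        return 0
    starts, ends = intervals[:, 0], intervals[:, 1]
    idx = np.searchsorted(starts, points, side="right") - 1
    inside = (idx >= 0) & (points < ends[np.maximum(idx, 0)])
    return int(np.count_nonzero(inside))


def projection_test(
    query_points: PointSet,
    reference: FeatureSet,
    space: GenomeSpace,
    scope: str | None = None,
    alpha: float = 0.05,
) -> ProjectionResult:
    """Exact two-sided binomial test of query points inside reference intervals.

    ``reference`` must be normalized (merged). ``scope`` is a chromosome
    name or None/"genome" for the concatenated genome, in which case hit
    counts and covered lengths are summed before the single binomial test.
    """
    chroms = _scope_chroms(space, scope)
    n_query = sum(query_points.n_points(c) for c in chroms)
    if n_query == 0:
        raise SkipScope("no query points in scope")
    n_hits = sum(_count_hits(query_points.on(c), reference.on(c)) for c in chroms)
    covered = sum(reference.total_bp(c) for c in chroms)
    total = sum(space.length(c) for c in chroms)
    coverage_p = covered / total
    p = float(stats.binomtest(n_hits, n_query, coverage_p).pvalue)
    expected = n_query * coverage_p
    if n_hits > expected and p < alpha:
        direction = "overlapping"
    elif n_hits < expected and p < alpha:
        direction = "nonoverlapping"
    else:
        direction = "none"
    return ProjectionResult(
        n_query=n_query,
        n_hits=n_hits,
        coverage_p=coverage_p,
        p=p,
        direction=direction,
        low_information=coverage_p < 0.01 or coverage_p > 0.99,
    )


def _coverage_prefix(intervals: np.ndarray):
    """Prefix representation of the coverage function of merged intervals.

    Returns (starts, ends, prefix) where prefix[i] is the covered bp strictly
    before interval i. F(x) = covered bp in [0, x) is then evaluable by
    binary search (see ``_eval_coverage``).
    """
    starts, ends = intervals[:, 0], intervals[:, 1]
    lengths = ends - starts
    prefix = np.concatenate(([0], np.cumsum(lengths)))
    return starts, ends, prefix


def _eval_coverage(x, starts, ends, prefix):
    """Covered bp of the merged interval set within [0, x), vectorized in x."""
    idx = np.searchsorted(starts, x, side="right") - 1
    safe = np.maximum(idx, 0)
    partial = np.clip(x - starts[safe], 0, ends[safe] - starts[safe])
    return np.where(idx >= 0, prefix[safe] + partial, 0)


def intersection_bp(a: np.ndarray, b: np.ndarray) -> int:
    """Base pairs shared by two merged interval arrays on one chromosome."""
    if len(a) == 0 or len(b) == 0:
        return 0
    starts, ends, prefix = _coverage_prefix(b)
    inter = _eval_coverage(a[:, 1], starts, ends, prefix) - _eval_coverage(
        a[:, 0], starts, ends, prefix
    )
    return int(inter.sum())


def jaccard_statistic(
    query: FeatureSet,
    reference: FeatureSet,
    space: GenomeSpace,
    scope: str | None = None,
) -> float:
    """J = |Q ∩ R| / |Q ∪ R| in bp over the scope; 0 (with a warning) if both empty.

    Both sets must be normalized. Symmetric in its two arguments.
    """
    chroms = _scope_chroms(space, scope)
    inter = sum(intersection_bp(query.on(c), reference.on(c)) for c in chroms)
    total_q = sum(query.total_bp(c) for c in chroms)
    total_r = sum(reference.total_bp(c) for c in chroms)
    union = total_q + total_r - inter
    if union == 0:
        warnings.warn("Jaccard undefined for two empty sets; returning 0.0")
        return 0.0
    return inter / union


def rotate_intervals(intervals: np.ndarray, shift: int, L: int) -> np.ndarray:
    """Circularly rotate merged intervals by ``shift`` bp on a ring of length L.

    Intervals that wrap the origin are split in two. The result is sorted
    and merged (a wrapped pair abutting at the origin stays split only if
    disjoint). Interval lengths and inter-interval gaps are preserved on
    the ring.
    """
    if len(intervals) == 0:
        return intervals.copy()
    s = (intervals[:, 0] + shift) % L
    e = s + (intervals[:, 1] - intervals[:, 0])
    out = []
    for si, ei in zip(s, e):
        if ei <= L:
            out.append((si, ei))
        else:
            out.append((si, L))
            out.append((0, ei - L))
    # merge in case a split pair abuts another interval at the seam
    return _merge(np.array(sorted(out), dtype=np.int64))


def _rotation_intersections(
    q: np.ndarray, r: np.ndarray, L: int, shifts: np.ndarray
) -> np.ndarray:
    """Intersection bp of (q rotated by each shift) with r, without splitting.

    The reference is extended periodically to [0, 2L); a query interval
    shifted to [a, a + len) with a in [0, L) then never needs wrapping.
    """
    if len(q) == 0 or len(r) == 0:
        return np.zeros(len(shifts))
    r2 = np.vstack([r, r + L])
    starts, ends, prefix = _coverage_prefix(r2)
    a = (q[:, 0][None, :] + shifts[:, None]) % L
    b = a + (q[:, 1] - q[:, 0])[None, :]
    inter = _eval_coverage(b, starts, ends, prefix) - _eval_coverage(
        a, starts, ends, prefix
    )
    return inter.sum(axis=1)


def _gap_shuffle_positions(q: np.ndarray, L: int, rng) -> np.ndarray:
    """Start positions after shuffling ring gaps and applying a random phase.

    Returns an (n, 2) array of possibly-unwrapped intervals in [0, 2L);
    callers evaluate coverage against a periodically extended reference.
    """
    lengths = q[:, 1] - q[:, 0]
    n = len(q)
    total_gap = L - int(lengths.sum())
    # ring gaps: gap i sits after interval i (wrapping from last to first)
    gaps = np.empty(n, dtype=np.int64)
    gaps[:-1] = q[1:, 0] - q[:-1, 1]
    gaps[-1] = total_gap - int(gaps[:-1].sum())
    rng.shuffle(gaps)
    phase = int(rng.integers(0, L))
    starts = phase + np.concatenate(([0], np.cumsum(lengths[:-1] + gaps[:-1])))
    starts %= L
    return np.column_stack([starts, starts + lengths])


def jaccard_permutation_test(
    query: FeatureSet,
    reference: FeatureSet,
    space: GenomeSpace,
    n_perm: int,
    rng,
    mode: str = "rotation",
    scope: str | None = None,
) -> tuple[float, str, float]:
    """Spacing-preserving permutation test of the Jaccard statistic.

    Returns (p, direction, observed J). Both sets must be normalized.
    mode="rotation": per chromosome, each permutation applies an independent
    uniform circular shift to the whole query set. mode="gap-shuffle":
    inter-interval ring gaps are permuted and a uniform phase applied.
    Two-sided p with add-one correction; direction from the permutation
    median.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if mode not in ("rotation", "gap-shuffle"):
        raise ValueError(f"unknown permutation mode: {mode!r}")
    rng = np.random.default_rng(rng)
    chroms = _scope_chroms(space, scope)
    if sum(query.n_intervals(c) for c in chroms) == 0:
        raise SkipScope("no query intervals in scope")
    total_q = sum(query.total_bp(c) for c in chroms)
    total_r = sum(reference.total_bp(c) for c in chroms)
    obs_inter = sum(intersection_bp(query.on(c), reference.on(c)) for c in chroms)
    obs_union = total_q + total_r - obs_inter
    J_obs = obs_inter / obs_union if obs_union else 0.0

    perm_inter = np.zeros(n_perm)
    for c in chroms:
        q, r = query.on(c), reference.on(c)
        if len(q) == 0:
            continue
        L = space.length(c)
        if mode == "rotation":
            shifts = rng.integers(0, L, size=n_perm)
            perm_inter += _rotation_intersections(q, r, L, shifts)
        else:
            if len(r):
                r2 = np.vstack([r, r + L])
                starts, ends, prefix = _coverage_prefix(r2)
                for k in range(n_perm):
                    pos = _gap_shuffle_positions(q, L, rng)
                    inter = _eval_coverage(pos[:, 1], starts, ends, prefix) - (
                        _eval_coverage(pos[:, 0], starts, ends, prefix)
                    )
                    perm_inter[k] += inter.sum()
            else:
                for k in range(n_perm):
                    _gap_shuffle_positions(q, L, rng)  # keep stream aligned
    J_perm = np.where(
        total_q + total_r - perm_inter > 0,
        perm_inter / (total_q + total_r - perm_inter),
        0.0,
    )
    p_ge = (1 + int(np.count_nonzero(J_perm >= J_obs))) / (n_perm + 1)
    p_le = (1 + int(np.count_nonzero(J_perm <= J_obs))) / (n_perm + 1)
    p = min(1.0, 2.0 * min(p_ge, p_le))
    med = float(np.median(J_perm))
    if J_obs > med:
        direction = "overlapping"
    elif J_obs < med:
        direction = "nonoverlapping"
    else:
        direction = "none"
    return p, direction, J_obs


def jaccard_test(
    query: FeatureSet,
    reference: FeatureSet,
    space: GenomeSpace,
    n_perm: int,
    rng,
    mode: str = "rotation",
    scope: str | None = None,
) -> JaccardResult:
    p, direction, J_obs = jaccard_permutation_test(
        query, reference, space, n_perm, rng, mode, scope
    )
    return JaccardResult(jaccard=J_obs, p=p, direction=direction, n_perm=n_perm)
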