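"""Absolute-distance test.

For each query point the distance to its nearest reference point is scaled
by the expected inter-reference gap of the chromosome, g = L / (n_ref + 1)
(n_ref points split a linear chromosome of length L into n_ref + 1
segments; g = L / n_ref is available as an alternative rule). The test
statistic is the mean scaled distance — the lower it is, the closer the
query sits to the reference. Unlike the relative-distance test, the
statistic keeps absolute scale, so it detects query points held at a
consistent small distance from reference points even when dense, unevenly
spaced references make the relative positions look uniform.

The null distribution depends on the reference configuration, so inference
is purely permutational: each permutation redraws every query point
uniformly on its chromosome, holding the references fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import SkipScope

__all__ = [
    "AbsoluteDistanceResult",
    "scaled_min_distances",
    "mean_statistic",
    "absolute_permutation_test",
    "absolute_distance_test",
]


@dataclass
class AbsoluteDistanceResult:
    n_query: int
    mean_scaled_distance: float
    p: float
    direction: str  # "closer" | "farther" | "none"

    statistic_name = "mean_scaled_distance"

    @property
    def statistic(self) -> float:
        return self.mean_scaled_distance


def expected_gap(chrom_length: int, n_ref: int, gap_rule: str = "n_plus_1") -> float:
    if n_ref < 1:
        raise SkipScope("no reference points on chromosome")
    if gap_rule == "n_plus_1":
        return chrom_length / (n_ref + 1)
    if gap_rule == "n":
        return chrom_length / n_ref
    raise ValueError(f"unknown gap_rule: {gap_rule!r}")


def _nearest_distance(
    query: np.ndarray, refs: np.ndarray, chrom_length: int, circular: bool
) -> np.ndarray:
    """Distance from each query position to the nearest reference position."""
    idx = np.searchsorted(refs, query)
    n = len(refs)
    left = np.where(idx > 0, query - refs[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
    right = np.where(idx < n, refs[np.minimum(idx, n - 1)] - query, np.iinfo(np.int64).max)
    raw = np.minimum(left, right)
    if circular:
        # wraparound: first reference seen from the right end and vice versa
        wrap = np.minimum(
            np.mod(query - refs[-1], chrom_length), np.mod(refs[0] - query, chrom_length)
        )
        raw = np.minimum(raw, wrap)
    return raw


def scaled_min_distances(
    query: np.ndarray,
    reference: np.ndarray,
    chrom_length: int,
    gap_rule: str = "n_plus_1",
    circular: bool = False,
) -> np.ndarray:
    """Per-query nearest-reference distances scaled by the expected gap."""
    query = np.asarray(query)
    refs = np.unique(np.asarray(reference))
    if len(query) == 0:
        raise SkipScope("no query points on chromosome")
    g = expected_gap(int(chrom_length), len(refs), gap_rule)
    return _nearest_distance(query, refs, int(chrom_length), circular) / g


def mean_statistic(d) -> float:
    """Mean scaled distance — the pooled test statistic."""
    d = np.asarray(d, dtype=np.float64)
    if d.size == 0:
        raise SkipScope("empty distance sample")
    return float(d.mean())


def permutation_means(
    reference: Mapping[str, np.ndarray],
    chrom_lengths: Mapping[str, int],
    n_query_per_chrom: Mapping[str, int],
    n_perm: int,
    rng,
    gap_rule: str = "n_plus_1",
    circular: bool = False,
) -> np.ndarray:
    """Pooled mean scaled distance for each of ``n_perm`` uniform redraws.

    Query counts per chromosome are held at their observed values; each
    permutation redraws all query positions uniformly on their chromosomes.
    """
    rng = np.random.default_rng(rng)
    total_n = sum(n_query_per_chrom.values())
    if total_n == 0:
        raise SkipScope("no query points in scope")
    sums = np.zeros(n_perm)
    for chrom, n_q in n_query_per_chrom.items():
        if n_q == 0:
            continue
        refs = np.unique(np.asarray(reference[chrom]))
        L = int(chrom_lengths[chrom])
        g = expected_gap(L, len(refs), gap_rule)
        draws = rng.integers(0, L, size=(n_perm, n_q))
        raw = _nearest_distance(draws.ravel(), refs, L, circular)
        sums += raw.reshape(n_perm, n_q).sum(axis=1) / g
    return sums / total_n


def absolute_permutation_test(
    stat_obs: float,
    reference: Mapping[str, np.ndarray],
    chrom_lengths: Mapping[str, int],
    n_query_per_chrom: Mapping[str, int],
    n_perm: int,
    rng,
    gap_rule: str = "n_plus_1",
    circular: bool = False,
) -> tuple[float, str]:
    """Two-sided permutation p-value and direction for the mean statistic.

    p = min(1, 2 * min(p_ge, p_le)) with the add-one correction on each
    tail; direction is "closer" when the observed mean falls below the
    permutation median, "farther" above it, "none" when equal.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    perm = permutation_means(
        reference, chrom_lengths, n_query_per_chrom, n_perm, rng, gap_rule, circular
    )
    p_ge = (1 + int(np.count_nonzero(perm >= stat_obs))) / (n_perm + 1)
    p_le = (1 + int(np.count_nonzero(perm <= stat_obs))) / (n_perm + 1)
    p = min(1.0, 2.0 * min(p_ge, p_le))
    med = float(np.median(perm))
    if stat_obs < med:
        direction = "closer"
    elif stat_obs > med:
        direction = "farther"
    else:
        direction = "none"
    return p, direction


def absolute_distance_test(
    query: Mapping[str, np.ndarray],
    reference: Mapping[str, np.ndarray],
    chrom_lengths: Mapping[str, int],
    n_perm: int,
    rng,
    gap_rule: str = "n_plus_1",
    circular: bool = False,
) -> AbsoluteDistanceResult:
    """Pooled absolute-distance test over the chromosomes in ``chrom_lengths``."""
    d_all = []
    n_per_chrom = {}
    for chrom in chrom_lengths:
        q = np.asarray(query.get(chrom, ()))
        if len(q) == 0 or len(np.asarray(reference.get(chrom, ()))) == 0:
            continue
        d_all.append(
            scaled_min_distances(
                q, reference[chrom], chrom_lengths[chrom], gap_rule, circular
            )
        )
        n_per_chrom[chrom] = len(q)
    if not d_all:
        raise SkipScope("no chromosome has both query and reference points")
    d_all = np.concatenate(d_all)
    obs = mean_statistic(d_all)
    refs_used = {c: reference[c] for c in n_per_chrom}
    lengths_used = {c: chrom_lengths[c] for c in n_per_chrom}
    p, direction = absolute_permutation_test(
        obs, refs_used, lengths_used, n_per_chrom, n_perm, rng, gap_rule, circular
    )
    return AbsoluteDistanceResult(
        n_query=len(d_all), mean_scaled_distance=obs, p=p, direction=direction
    )
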