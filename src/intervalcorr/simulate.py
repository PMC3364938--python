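"""Synthetic interval sets with known spatial relationships.

Every test and acceptance experiment in this package runs on data from this
generator, so each relationship encodes a ground truth the association
statistics should recover:

* ``independent`` — query and reference placed uniformly and independently;
  the null for every test.
* ``coincident`` — query midpoints drawn from the reference midpoints;
  perfect attraction (relative-distance correlation +1).
* ``fixed_offset`` — every query exactly ``offset`` bp from a reference
  midpoint (random side); the constant-spacing regime the absolute test
  targets.
* ``attraction`` — query displaced from references by two-sided
  geometric-decay (discretized Laplace) noise of the given scale.
* ``repulsion`` — query placed uniformly within the middle third of
  inter-reference ring gaps; forces relative distances toward 1/2.
* ``spike_in`` — a fraction of query points at a small uniform offset from
  a reference, the rest at offsets spanning many inter-reference gaps, so
  the spike is visible to the absolute-distance test but diluted for the
  relative-distance test.
* ``asymmetric`` — a sparse query set all near members of a much denser
  uniform reference; association is detectable with the sparse set as
  query but not in the reverse direction.

Default geometry is 4 chromosomes of 1 Mb; features default to 1 bp so
midpoint reduction is the identity in baseline tests. All placement is on
the chromosome ring (offsets wrap), keeping stated offsets exact; offsets
must be smaller than the chromosome.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np

from .genome import FeatureSet

__all__ = ["SimSpec", "simulate", "default_genome"]

RELATIONSHIPS = (
    "independent",
    "coincident",
    "fixed_offset",
    "attraction",
    "repulsion",
    "spike_in",
    "asymmetric",
)


def default_genome(n_chroms: int = 4, length: int = 1_000_000) -> dict[str, int]:
    return {f"chr{i}": length for i in range(1, n_chroms + 1)}


@dataclass
class SimSpec:
    """Declarative description of one simulated query/reference pair."""

    relationship: str = "independent"
    chrom_lengths: dict[str, int] = field(default_factory=default_genome)
    n_reference: int = 1000
    n_query: int = 1000
    reference_length: int = 1
    query_length: int = 1
    seed: int = 0
    # fixed_offset
    offset: int = 100
    # attraction
    scale: float = 100.0
    # spike_in
    spike_fraction: float = 0.1
    spike_offset_range: tuple[int, int] = (75, 100)
    background_offset_range: tuple[int, int] = (10, 10_000)
    # asymmetric (n_query/n_reference are ignored; these counts rule)
    sparse_n: int = 12
    dense_n: int = 5000
    near_offset_max: int = 20

    def __post_init__(self):
        if self.relationship not in RELATIONSHIPS:
            raise ValueError(f"unknown relationship: {self.relationship!r}")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be nonempty")
        if min(self.chrom_lengths.values()) <= 0:
            raise ValueError("chromosome lengths must be positive")
        for count in (self.n_reference, self.n_query):
            if count <= 0:
                raise ValueError("feature counts must be positive")
        min_L = min(self.chrom_lengths.values())
        max_offset = {
            "fixed_offset": self.offset,
            "spike_in": max(
                self.spike_offset_range[1], self.background_offset_range[1]
            ),
            "asymmetric": self.near_offset_max,
        }.get(self.relationship, 0)
        if max_offset >= min_L:
            raise ValueError(
                f"offset {max_offset} is not smaller than the shortest "
                f"chromosome ({min_L} bp)"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimSpec":
        data = json.loads(text)
        for key in ("spike_offset_range", "background_offset_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _uniform_midpoints(
    rng, chrom_lengths: Mapping[str, int], n: int
) -> dict[str, np.ndarray]:
    """n midpoints placed uniformly genome-wide (chromosome chosen by length)."""
    names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in names], dtype=np.float64)
    which = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    out = {}
    for i, name in enumerate(names):
        k = int(np.count_nonzero(which == i))
        if k:
            out[name] = rng.integers(0, chrom_lengths[name], size=k)
    return out


def _anchors(rng, ref_mids: dict[str, np.ndarray], n: int) -> list[tuple[str, int]]:
    """n reference midpoints sampled with replacement across the genome."""
    flat = [(c, int(m)) for c, mids in ref_mids.items() for m in mids]
    idx = rng.integers(0, len(flat), size=n)
    return [flat[i] for i in idx]


def _offsets_to_points(
    anchors: list[tuple[str, int]],
    offsets: np.ndarray,
    signs: np.ndarray,
    chrom_lengths: Mapping[str, int],
) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for (chrom, mid), off, sign in zip(anchors, offsets, signs):
        pos = (mid + int(sign) * int(off)) % chrom_lengths[chrom]
        out.setdefault(chrom, []).append(pos)
    return {c: np.array(v, dtype=np.int64) for c, v in out.items()}


def _mids_to_features(
    mids: Mapping[str, np.ndarray],
    length: int,
    chrom_lengths: Mapping[str, int],
    label: str,
) -> FeatureSet:
    """Build intervals whose midpoint (rounding down) is the given position."""
    ivals = {}
    for chrom, m in mids.items():
        L = chrom_lengths[chrom]
        start = np.clip(np.asarray(m) - (length - 1) // 2, 0, max(L - length, 0))
        ivals[chrom] = np.column_stack([start, start + length])
    return FeatureSet(ivals, label=label)


def simulate(spec: SimSpec) -> tuple[FeatureSet, FeatureSet, dict]:
    """Generate (query, reference, truth) for the requested relationship."""
    rng = np.random.default_rng(spec.seed)
    lengths = spec.chrom_lengths
    rel = spec.relationship

    if rel == "asymmetric":
        n_ref, n_query = spec.dense_n, spec.sparse_n
    else:
        n_ref, n_query = spec.n_reference, spec.n_query
    ref_mids = _uniform_midpoints(rng, lengths, n_ref)

    if rel == "independent":
        q_mids = _uniform_midpoints(rng, lengths, n_query)
    elif rel == "coincident":
        # use each reference midpoint at most once so that equal counts give
        # a perfectly symmetric pairing (resample only when query outnumbers
        # reference)
        flat = [(c, int(m)) for c, mids in ref_mids.items() for m in mids]
        if n_query >= len(flat):
            idx = np.r_[np.arange(len(flat)),
                        rng.integers(0, len(flat), size=n_query - len(flat))]
        else:
            idx = rng.choice(len(flat), size=n_query, replace=False)
        anchors = [flat[i] for i in idx]
        q_mids = _offsets_to_points(
            anchors, np.zeros(n_query, dtype=np.int64), np.ones(n_query), lengths
        )
    elif rel == "fixed_offset":
        anchors = _anchors(rng, ref_mids, n_query)
        offs = np.full(n_query, spec.offset, dtype=np.int64)
        signs = rng.choice([-1, 1], size=n_query)
        q_mids = _offsets_to_points(anchors, offs, signs, lengths)
    elif rel == "attraction":
        anchors = _anchors(rng, ref_mids, n_query)
        offs = np.rint(rng.laplace(0.0, spec.scale, size=n_query)).astype(np.int64)
        q_mids = _offsets_to_points(
            anchors, np.abs(offs), np.sign(offs) + (offs == 0), lengths
        )
    elif rel == "repulsion":
        q_mids = {}
        counts = _chrom_counts(rng, lengths, n_query)
        for chrom, k in counts.items():
            if k == 0 or chrom not in ref_mids:
                continue
            mids = np.unique(ref_mids[chrom])
            L = lengths[chrom]
            gaps = np.diff(np.concatenate([mids, [mids[0] + L]]))  # ring gaps
            pick = rng.choice(len(gaps), size=k, p=gaps / gaps.sum())
            u = rng.uniform(1 / 3, 2 / 3, size=k)
            q_mids[chrom] = ((mids[pick] + (u * gaps[pick])).astype(np.int64)) % L
    elif rel == "spike_in":
        n_spike = int(round(spec.spike_fraction * n_query))
        anchors = _anchors(rng, ref_mids, n_query)
        lo_s, hi_s = spec.spike_offset_range
        lo_b, hi_b = spec.background_offset_range
        offs = np.concatenate(
            [
                rng.integers(lo_s, hi_s + 1, size=n_spike),
                rng.integers(lo_b, hi_b + 1, size=n_query - n_spike),
            ]
        )
        signs = rng.choice([-1, 1], size=n_query)
        q_mids = _offsets_to_points(anchors, offs, signs, lengths)
    elif rel == "asymmetric":
        anchors = _anchors(rng, ref_mids, n_query)
        offs = rng.integers(0, spec.near_offset_max + 1, size=n_query)
        signs = rng.choice([-1, 1], size=n_query)
        q_mids = _offsets_to_points(anchors, offs, signs, lengths)

    query = _mids_to_features(q_mids, spec.query_length, lengths, f"query:{rel}")
    reference = _mids_to_features(
        ref_mids, spec.reference_length, lengths, f"reference:{rel}"
    )
    truth = {
        "relationship": rel,
        "seed": spec.seed,
        "n_query": n_query,
        "n_reference": n_ref,
        "params": {
            k: v
            for k, v in asdict(spec).items()
            if k not in ("chrom_lengths", "relationship", "seed")
        },
    }
    return query, reference, truth


def _chrom_counts(rng, chrom_lengths: Mapping[str, int], n: int) -> dict[str, int]:
    names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in names], dtype=np.float64)
    counts = rng.multinomial(n, lengths / lengths.sum())
    return dict(zip(names, counts))
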