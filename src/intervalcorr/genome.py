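"""Coordinate system, interval containers and file I/O.

All coordinates are held internally as 0-based half-open intervals (the BED
convention). GFF input (1-based, closed) is converted on read by subtracting
one from the start. Strand is ignored throughout: none of the association
statistics in this package are strand-aware.

A :class:`GenomeSpace` fixes the coordinate universe — an ordered set of named
chromosomes with integer lengths — and every downstream statistic is computed
per chromosome within it. Feature collections are held as
:class:`FeatureSet` (sorted interval arrays per chromosome) or, after midpoint
reduction, as :class:`PointSet` (sorted integer positions per chromosome).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomeSpace",
    "FeatureSet",
    "PointSet",
    "read_chrom_sizes",
    "read_features",
    "midpoints",
    "normalize",
    "coverage_fraction",
    "restrict",
    "write_bed",
]


def _open_text(path) -> io.TextIOBase:
    """Open a plain or gzip-compressed text file for reading."""
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


class GenomeSpace:
    """Ordered map of chromosome name -> length in bp.

    Lengths must be positive and names unique; insertion order is preserved
    and defines the reporting order of per-chromosome results.
    """

    def __init__(self, chromosomes: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        self._chroms: dict[str, int] = {}
        items = chromosomes.items() if isinstance(chromosomes, Mapping) else chromosomes
        for name, length in items:
            self.add(name, length)

    def add(self, name: str, length: int) -> None:
        if name in self._chroms:
            raise ValueError(f"duplicate chromosome name: {name!r}")
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._chroms[name] = length

    def __len__(self) -> int:
        return len(self._chroms)

    def __iter__(self) -> Iterator[str]:
        return iter(self._chroms)

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def __getitem__(self, name: str) -> int:
        return self._chroms[name]

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSpace) and self._chroms == other._chroms

    def __repr__(self) -> str:
        inner = ", ".join(f"{n}:{l}" for n, l in self._chroms.items())
        return f"GenomeSpace({{{inner}}})"

    @property
    def names(self) -> list[str]:
        return list(self._chroms)

    @property
    def total_length(self) -> int:
        return sum(self._chroms.values())

    def length(self, name: str) -> int:
        if name not in self._chroms:
            raise KeyError(f"unknown chromosome: {name!r}")
        return self._chroms[name]


_EMPTY_IVALS = np.empty((0, 2), dtype=np.int64)


@dataclass
class FeatureSet:
    """Per-chromosome sorted interval collections.

    ``intervals[chrom]`` is an ``(n, 2)`` int64 array of ``[start, end)``
    pairs sorted by start. The query/reference role is assigned at run time,
    not stored here. ``label`` records provenance (file path or generator
    relationship) for reporting.
    """

    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        for chrom, arr in list(self.intervals.items()):
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            self.intervals[chrom] = arr[order]

    def chroms(self) -> list[str]:
        return list(self.intervals)

    def on(self, chrom: str) -> np.ndarray:
        return self.intervals.get(chrom, _EMPTY_IVALS)

    def n_intervals(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.on(chrom))
        return sum(len(a) for a in self.intervals.values())

    def total_bp(self, chrom: str | None = None) -> int:
        chroms = [chrom] if chrom is not None else self.chroms()
        return int(sum((self.on(c)[:, 1] - self.on(c)[:, 0]).sum() for c in chroms))

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureSet):
            return NotImplemented
        mine = {c: a for c, a in self.intervals.items() if len(a)}
        theirs = {c: a for c, a in other.intervals.items() if len(a)}
        return mine.keys() == theirs.keys() and all(
            np.array_equal(mine[c], theirs[c]) for c in mine
        )


@dataclass
class PointSet:
    """Per-chromosome sorted integer positions (bp), duplicates retained."""

    points: dict[str, np.ndarray] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        for chrom, arr in list(self.points.items()):
            self.points[chrom] = np.sort(np.asarray(arr, dtype=np.int64))

    def chroms(self) -> list[str]:
        return list(self.points)

    def on(self, chrom: str) -> np.ndarray:
        return self.points.get(chrom, np.empty(0, dtype=np.int64))

    def n_points(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.on(chrom))
        return sum(len(a) for a in self.points.values())


def read_chrom_sizes(path) -> GenomeSpace:
    """Read a two-column ``name<TAB>length`` table into a GenomeSpace.

    Blank lines are skipped; any whitespace delimits the two columns. An
    empty file yields an empty (valid) GenomeSpace.
    """
    space = GenomeSpace()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            name, raw_len = parts[0], parts[1]
            try:
                length = int(raw_len)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: length {raw_len!r} is not an integer"
                ) from None
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length {length}")
            if name in space:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome name {name!r}")
            space.add(name, length)
    return space


def read_features(
    path,
    format: str,
    space: GenomeSpace,
    skip_unknown: bool = False,
    label: str | None = None,
) -> FeatureSet:
    """Read a BED or GFF file into a FeatureSet within ``space``.

    BED records are taken as-is (0-based half-open, columns 1–3, extra
    columns ignored). GFF records use columns 4 and 5 (1-based closed) and
    are converted by ``start - 1``. Records on chromosomes not in ``space``
    raise unless ``skip_unknown`` is set, in which case they are counted on
    the returned set's ``skipped_unknown`` attribute.
    """
    format = format.lower()
    if format not in ("bed", "gff"):
        raise ValueError(f"unsupported format: {format!r} (expected 'bed' or 'gff')")
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    skipped = 0
    with _open_text(path) as fh:
        for recno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            try:
                if format == "bed":
                    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                else:
                    chrom, start, end = cols[0], int(cols[3]) - 1, int(cols[4])
            except (IndexError, ValueError):
                raise ValueError(f"{path}: malformed record {recno}: {line!r}") from None
            if chrom not in space:
                if skip_unknown:
                    skipped += 1
                    continue
                raise ValueError(
                    f"{path}: record {recno} on unknown chromosome {chrom!r}"
                )
            if end <= start:
                raise ValueError(
                    f"{path}: record {recno} has end <= start ({start}, {end})"
                )
            if start < 0 or end > space[chrom]:
                raise ValueError(
                    f"{path}: record {recno} [{start}, {end}) exceeds "
                    f"chromosome {chrom!r} bounds [0, {space[chrom]})"
                )
            per_chrom.setdefault(chrom, []).append((start, end))
    fs = FeatureSet(
        {c: np.array(v, dtype=np.int64) for c, v in per_chrom.items()},
        label=label if label is not None else str(path),
    )
    fs.skipped_unknown = skipped
    return fs


def write_bed(fs: FeatureSet, path) -> None:
    """Write a FeatureSet as 3-column BED (plain or .gz by extension)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for chrom in fs.chroms():
            for start, end in fs.on(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\n")


def midpoints(fs: FeatureSet, label: str | None = None) -> PointSet:
    """Reduce each interval [s, e) to its midpoint base floor((s + e - 1) / 2).

    This is the midpoint of the covered bases, rounding down for even-length
    intervals; a single-base interval maps to itself. Sorted order is
    preserved per chromosome and duplicate midpoints are retained.
    """
    pts = {}
    for chrom in fs.chroms():
        arr = fs.on(chrom)
        if len(arr):
            pts[chrom] = (arr[:, 0] + arr[:, 1] - 1) // 2
    return PointSet(pts, label=label if label is not None else fs.label)


def _merge(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping/abutting sorted intervals."""
    if len(arr) <= 1:
        return arr.copy()
    starts, ends = arr[:, 0], np.maximum.accumulate(arr[:, 1])
    # a new block begins where the start exceeds the running max end
    new_block = np.r_[True, starts[1:] > ends[:-1]]
    out_starts = starts[new_block]
    out_ends = np.maximum.reduceat(arr[:, 1], np.flatnonzero(new_block))
    return np.column_stack([out_starts, out_ends]).astype(np.int64)


def normalize(fs: FeatureSet) -> FeatureSet:
    """Merge overlapping or abutting intervals; total covered bp is invariant."""
    return FeatureSet(
        {c: _merge(fs.on(c)) for c in fs.chroms() if len(fs.on(c))}, label=fs.label
    )


def coverage_fraction(fs: FeatureSet, space: GenomeSpace, chrom: str) -> float:
    """Fraction of ``chrom`` covered by ``fs`` (which must be normalized)."""
    length = space.length(chrom)
    return fs.total_bp(chrom) / length


def restrict(
    fs: FeatureSet, mask: FeatureSet, space: GenomeSpace
) -> tuple[FeatureSet, GenomeSpace]:
    """Clip ``fs`` to ``mask`` intervals, each becoming a pseudo-chromosome.

    Every mask interval [s, e) on chromosome ``c`` becomes a pseudo-chromosome
    named ``"c:s-e"`` of length ``e - s``; intervals of ``fs`` are clipped to
    it and shifted into its local coordinates. Intervals outside the mask are
    dropped. Query and reference must both be restricted with the same mask
    before any test is run on the restricted space.
    """
    if mask.n_intervals() == 0:
        raise ValueError("empty mask: nothing to restrict to")
    new_space = GenomeSpace()
    new_ivals: dict[str, np.ndarray] = {}
    for chrom in mask.chroms():
        if chrom not in space:
            raise KeyError(f"mask on unknown chromosome {chrom!r}")
        arr = fs.on(chrom)
        for ms, me in mask.on(chrom):
            name = f"{chrom}:{ms}-{me}"
            new_space.add(name, me - ms)
            if not len(arr):
                continue
            clipped_start = np.maximum(arr[:, 0], ms)
            clipped_end = np.minimum(arr[:, 1], me)
            keep = clipped_start < clipped_end
            if keep.any():
                new_ivals[name] = np.column_stack(
                    [clipped_start[keep] - ms, clipped_end[keep] - ms]
                )
    return FeatureSet(new_ivals, label=fs.label), new_space
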