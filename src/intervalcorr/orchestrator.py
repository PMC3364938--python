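"""End-to-end execution: load data, run every requested test per scope and
direction, and serialize the report.

Almost all of the tests are asymmetric — one set is held fixed as the
reference while the query is evaluated against it — and real relationships
are often visible in only one direction, so by default every comparison is
run both ways. Results are reported per chromosome and for the pooled
genome: the distance-based tests pool their per-chromosome distance vectors
before testing, while the overlap tests sum counts and covered lengths
(permutations still act per chromosome).

Reproducibility: each (direction, scope, test) triple gets its own random
substream derived from the master seed by a stable hash, so results are
bit-identical across runs and invariant to which other tests are requested.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import absolute, overlap, relative
from .config import RunConfig
from .errors import SkipScope
from .genome import (
    FeatureSet,
    GenomeSpace,
    PointSet,
    midpoints,
    normalize,
    read_chrom_sizes,
    read_features,
    restrict,
)

__all__ = ["Report", "run", "run_tests", "write_report", "plot_summary", "substream"]

logger = logging.getLogger(__name__)

GENOME_SCOPE = "genome"


def substream(seed: int, *key_parts) -> np.random.Generator:
    """Deterministic RNG substream for a (direction, scope, test) key."""
    key = "|".join(str(p) for p in key_parts)
    return np.random.default_rng([int(seed), zlib.crc32(key.encode()) & 0x7FFFFFFF])


@dataclass
class Report:
    meta: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)  # direction -> scope -> test -> record
    skipped: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {"meta": self.meta, "skipped": self.skipped, "results": {}}
        for direction, scopes in self.results.items():
            out["results"][direction] = {}
            for scope, tests in scopes.items():
                out["results"][direction][scope] = {
                    t: dataclasses.asdict(r) for t, r in tests.items()
                }
        return out

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per direction x scope x test."""
        rows = []
        for direction, scopes in self.results.items():
            for scope, tests in scopes.items():
                for test, r in tests.items():
                    rows.append(
                        {
                            "direction": direction,
                            "scope": scope,
                            "test": test,
                            "statistic_name": r.statistic_name,
                            "statistic": r.statistic,
                            "p": r.p,
                            "effect_direction": r.direction,
                            "n": getattr(r, "n_query", ""),
                        }
                    )
        columns = [
            "direction", "scope", "test", "statistic_name",
            "statistic", "p", "effect_direction", "n",
        ]
        return pd.DataFrame(rows, columns=columns)


def _distance_inputs(fs: FeatureSet) -> PointSet:
    """Midpoint reduction with per-chromosome deduplication (reference role)."""
    pts = midpoints(fs)
    return PointSet({c: np.unique(pts.on(c)) for c in pts.chroms()}, label=pts.label)


def run_tests(
    query: FeatureSet,
    reference: FeatureSet,
    space: GenomeSpace,
    config: RunConfig,
    direction_label: str = "query_vs_reference",
    report: Report | None = None,
    collect_distances: dict | None = None,
) -> Report:
    """Run the configured tests for one direction; append into ``report``."""
    if report is None:
        report = Report()
    res_dir = report.results.setdefault(direction_label, {})
    q_pts = midpoints(query)  # duplicates retained: repeated sites are data
    r_pts = _distance_inputs(reference)
    r_norm = normalize(reference)
    q_norm = normalize(query)

    scopes = list(space.names) + [GENOME_SCOPE]
    pooled_rel: list[np.ndarray] = []
    pooled_abs: list[np.ndarray] = []
    abs_refs: dict[str, np.ndarray] = {}
    abs_lengths: dict[str, int] = {}
    abs_counts: dict[str, int] = {}
    rel_dropped = 0

    def record_skip(scope, test, reason):
        report.skipped.append(
            {"direction": direction_label, "scope": scope, "test": test,
             "reason": reason}
        )
        logger.warning("%s/%s/%s skipped: %s", direction_label, scope, test, reason)

    for scope in scopes:
        res_scope = res_dir.setdefault(scope, {})
        is_genome = scope == GENOME_SCOPE

        if "relative" in config.tests:
            try:
                if is_genome:
                    if not pooled_rel:
                        raise SkipScope("no chromosome yielded relative distances")
                    d = np.concatenate(pooled_rel)
                    n_drop = rel_dropped
                else:
                    d = relative.relative_distances(
                        q_pts.on(scope), r_pts.on(scope), space.length(scope),
                        config.edge_mode,
                    )
                    n_drop = len(q_pts.on(scope)) - len(d)
                    rel_dropped += n_drop
                    pooled_rel.append(d)
                rng = substream(config.seed, direction_label, scope, "relative")
                res_scope["relative"] = relative.relative_distance_test(
                    d, config.n_perm, rng, config.alpha, n_dropped=n_drop
                )
                if collect_distances is not None:
                    collect_distances.setdefault("relative", {})[scope] = d
            except SkipScope as exc:
                record_skip(scope, "relative", exc.reason)

        if "absolute" in config.tests:
            try:
                if is_genome:
                    if not pooled_abs:
                        raise SkipScope("no chromosome yielded absolute distances")
                    d = np.concatenate(pooled_abs)
                    obs = absolute.mean_statistic(d)
                    rng = substream(config.seed, direction_label, scope, "absolute")
                    p, eff = absolute.absolute_permutation_test(
                        obs, abs_refs, abs_lengths, abs_counts,
                        config.n_perm, rng, config.gap_rule,
                    )
                    res_scope["absolute"] = absolute.AbsoluteDistanceResult(
                        n_query=len(d), mean_scaled_distance=obs, p=p, direction=eff
                    )
                else:
                    if len(r_pts.on(scope)) == 0:
                        raise SkipScope("no reference points on chromosome")
                    d = absolute.scaled_min_distances(
                        q_pts.on(scope), r_pts.on(scope), space.length(scope),
                        config.gap_rule,
                    )
                    pooled_abs.append(d)
                    abs_refs[scope] = r_pts.on(scope)
                    abs_lengths[scope] = space.length(scope)
                    abs_counts[scope] = len(d)
                    obs = absolute.mean_statistic(d)
                    rng = substream(config.seed, direction_label, scope, "absolute")
                    p, eff = absolute.absolute_permutation_test(
                        obs, {scope: r_pts.on(scope)}, {scope: space.length(scope)},
                        {scope: len(d)}, config.n_perm, rng, config.gap_rule,
                    )
                    res_scope["absolute"] = absolute.AbsoluteDistanceResult(
                        n_query=len(d), mean_scaled_distance=obs, p=p, direction=eff
                    )
                if collect_distances is not None:
                    collect_distances.setdefault("absolute", {})[scope] = d
            except SkipScope as exc:
                record_skip(scope, "absolute", exc.reason)

        if "projection" in config.tests:
            try:
                res_scope["projection"] = overlap.projection_test(
                    q_pts, r_norm, space,
                    None if is_genome else scope, config.alpha,
                )
            except SkipScope as exc:
                record_skip(scope, "projection", exc.reason)

        if "jaccard" in config.tests:
            try:
                rng = substream(config.seed, direction_label, scope, "jaccard")
                res_scope["jaccard"] = overlap.jaccard_test(
                    q_norm, r_norm, space, config.n_perm, rng,
                    config.jaccard_perm, None if is_genome else scope,
                )
            except SkipScope as exc:
                record_skip(scope, "jaccard", exc.reason)

        if not res_scope:
            del res_dir[scope]
    return report


def run(config: RunConfig) -> Report:
    """Load inputs per ``config``, run all tests in both directions, report."""
    space = read_chrom_sizes(config.genome)
    if len(space) == 0:
        raise ValueError("empty genome: no chromosomes to test")
    query = read_features(config.query, config.query_format, space, label="query")
    reference = read_features(
        config.reference, config.reference_format, space, label="reference"
    )
    if config.mask:
        mask = normalize(read_features(config.mask, "bed", space, label="mask"))
        if mask.n_intervals() == 0:
            raise ValueError("mask file contains no intervals")
        query, masked_space = restrict(query, mask, space)
        reference, space = restrict(reference, mask, space)
        assert masked_space == space

    report = Report(
        meta={
            "config": config.asdict(),
            "chromosomes": {c: space.length(c) for c in space.names},
            "n_query_intervals": query.n_intervals(),
            "n_reference_intervals": reference.n_intervals(),
        }
    )
    distances: dict = {}
    run_tests(query, reference, space, config, "query_vs_reference",
              report, distances)
    if config.both_directions:
        run_tests(reference, query, space, config, "reference_vs_query", report)

    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    write_report(report, outdir)
    if config.plots:
        try:
            plot_summary(
                distances.get("relative", {}),
                distances.get("absolute", {}),
                outdir / "plots" / "summary.pdf",
            )
        except Exception as exc:  # plots are best-effort; stats are on disk
            logger.warning("plotting failed (non-fatal): %s", exc)
    return report


def write_report(report: Report, outdir, formats=("json", "tsv")) -> list[Path]:
    """Write report.json (full nesting) and report.tsv (flat rows)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        path = outdir / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        written.append(path)
    if "tsv" in formats:
        path = outdir / "report.tsv"
        report.to_frame().to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def plot_summary(
    relative_distances: dict, absolute_distances: dict, outpath
) -> Path:
    """One page per scope: relative-distance ECDF vs the y = 2x null line,
    and a histogram of scaled absolute distances with their mean marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    outpath = Path(outpath)
    outpath.parent.mkdir(parents=True, exist_ok=True)
    scopes = sorted(
        set(relative_distances) | set(absolute_distances),
        key=lambda s: (s == GENOME_SCOPE, s),
    )
    with PdfPages(outpath) as pdf:
        for scope in scopes:
            fig, axes = plt.subplots(1, 2, figsize=(9, 3.6))
            d_rel = relative_distances.get(scope)
            if d_rel is not None and len(d_rel):
                xs = np.sort(d_rel)
                ys = np.arange(1, len(xs) + 1) / len(xs)
                axes[0].step(xs, ys, where="post", label="observed ECDF")
                axes[0].plot([0, 0.5], [0, 1], "k--", label="uniform null")
                axes[0].set_xlim(0, 0.5)
                axes[0].legend(fontsize=8)
            axes[0].set_xlabel("relative distance d")
            axes[0].set_ylabel("ECDF")
            d_abs = absolute_distances.get(scope)
            if d_abs is not None and len(d_abs):
                axes[1].hist(d_abs, bins=40, color="steelblue")
                axes[1].axvline(
                    float(np.mean(d_abs)), color="crimson", label="mean"
                )
                axes[1].legend(fontsize=8)
            axes[1].set_xlabel("scaled absolute distance")
            axes[1].set_ylabel("count")
            fig.suptitle(scope)
            fig.tight_layout()
            pdf.savefig(fig)
            plt.close(fig)
    return outpath
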