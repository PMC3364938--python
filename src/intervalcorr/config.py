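"""Run configuration: a declarative record of one analysis.

Configs can be built directly, or read from an INI-style file with three
sections so a run is fully archivable::

    [data]
    query = query.bed
    query_format = bed
    reference = reference.bed
    reference_format = bed
    genome = genome.sizes
    mask = mask.bed          ; optional

    [tests]
    tests = relative, absolute, projection, jaccard
    n_perm = 1000

    [options]
    seed = 1
    edge_mode = circular     ; or: drop
    gap_rule = n_plus_1      ; or: n
    jaccard_perm = rotation  ; or: gap-shuffle
    both_directions = true
    alpha = 0.05
    out = results/
    plots = false
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, fields

ALL_TESTS = ("relative", "absolute", "projection", "jaccard")


@dataclass
class RunConfig:
    query: str = ""
    reference: str = ""
    genome: str = ""
    query_format: str = "bed"
    reference_format: str = "bed"
    mask: str | None = None
    tests: tuple[str, ...] = ALL_TESTS
    n_perm: int = 1000
    seed: int = 0
    edge_mode: str = "circular"
    gap_rule: str = "n_plus_1"
    jaccard_perm: str = "rotation"
    both_directions: bool = True
    alpha: float = 0.05
    out: str = "."
    plots: bool = False

    def __post_init__(self):
        self.tests = tuple(self.tests)
        unknown = set(self.tests) - set(ALL_TESTS)
        if unknown:
            raise ValueError(f"unknown tests: {sorted(unknown)}")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        if self.edge_mode not in ("circular", "drop"):
            raise ValueError(f"bad edge_mode: {self.edge_mode!r}")
        if self.gap_rule not in ("n_plus_1", "n"):
            raise ValueError(f"bad gap_rule: {self.gap_rule!r}")
        if self.jaccard_perm not in ("rotation", "gap-shuffle"):
            raise ValueError(f"bad jaccard_perm: {self.jaccard_perm!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_ini(cls, path, **overrides) -> "RunConfig":
        """Read a config file; keyword overrides win over file values."""
        parser = configparser.ConfigParser(inline_comment_prefixes=(";", "#"))
        with open(path) as fh:
            parser.read_file(fh)
        kwargs: dict = {}
        data = parser["data"] if parser.has_section("data") else {}
        for key in ("query", "reference", "genome", "mask", "query_format",
                    "reference_format"):
            if key in data:
                kwargs[key] = data[key]
        tests_sec = parser["tests"] if parser.has_section("tests") else {}
        if "tests" in tests_sec:
            kwargs["tests"] = tuple(
                t.strip() for t in tests_sec["tests"].split(",") if t.strip()
            )
        if "n_perm" in tests_sec:
            kwargs["n_perm"] = int(tests_sec["n_perm"])
        opts = parser["options"] if parser.has_section("options") else {}
        for key in ("edge_mode", "gap_rule", "jaccard_perm", "out"):
            if key in opts:
                kwargs[key] = opts[key]
        if "seed" in opts:
            kwargs["seed"] = int(opts["seed"])
        if "alpha" in opts:
            kwargs["alpha"] = float(opts["alpha"])
        for key in ("both_directions", "plots"):
            if key in opts:
                kwargs[key] = opts[key].strip().lower() in ("1", "true", "yes", "on")
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)

    def asdict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["tests"] = list(out["tests"])  # JSON-stable form
        return out
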