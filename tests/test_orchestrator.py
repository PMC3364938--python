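import json

import numpy as np
import pytest
from click.testing import CliRunner

import intervalcorr as ic
from intervalcorr.cli import main as cli_main
from intervalcorr.simulate import SimSpec, simulate


def write_dataset(tmp_path, relationship="coincident", seed=0, **kwargs):
    spec = SimSpec(relationship=relationship, seed=seed, **kwargs)
    query, reference, _ = simulate(spec)
    ic.write_bed(query, tmp_path / "query.bed")
    ic.write_bed(reference, tmp_path / "reference.bed")
    with open(tmp_path / "genome.sizes", "w") as fh:
        for name, length in spec.chrom_lengths.items():
            fh.write(f"{name}\t{length}\n")
    return spec


def base_config(tmp_path, **kwargs):
    defaults = dict(
        query=str(tmp_path / "query.bed"),
        reference=str(tmp_path / "reference.bed"),
        genome=str(tmp_path / "genome.sizes"),
        n_perm=150,
        seed=1,
        out=str(tmp_path / "out"),
    )
    defaults.update(kwargs)
    return ic.RunConfig(**defaults)


class TestRun:
    def test_coincident_data_gives_unit_correlation_both_ways(self, tmp_path):
        write_dataset(tmp_path, "coincident", n_reference=100, n_query=100)
        report = ic.run(base_config(tmp_path, tests=("relative",)))
        fwd = report.results["query_vs_reference"]["genome"]["relative"]
        rev = report.results["reference_vs_query"]["genome"]["relative"]
        assert fwd.correlation == pytest.approx(1.0)
        assert rev.correlation == pytest.approx(1.0)
        assert fwd.direction == rev.direction == "closer"

    def test_single_test_config_yields_only_that_record(self, tmp_path):
        write_dataset(tmp_path, "independent", n_reference=50, n_query=50)
        report = ic.run(base_config(tmp_path, tests=("jaccard",)))
        for scopes in report.results.values():
            for tests in scopes.values():
                assert set(tests) == {"jaccard"}

    def test_rerun_reproduces_report_bytes(self, tmp_path):
        write_dataset(tmp_path, "attraction", n_reference=60, n_query=60)
        ic.run(base_config(tmp_path))
        first = (tmp_path / "out" / "report.json").read_bytes()
        ic.run(base_config(tmp_path))
        assert (tmp_path / "out" / "report.json").read_bytes() == first

    def test_other_chromosomes_unaffected_by_removal_of_one(self, tmp_path):
        spec = write_dataset(
            tmp_path, "attraction", n_reference=200, n_query=200, seed=3
        )
        cfg = base_config(tmp_path, tests=("relative", "absolute"))
        full = ic.run(cfg)

        # drop chr1 from both feature sets and from the genome
        space = ic.read_chrom_sizes(cfg.genome)
        keep = [c for c in space.names if c != "chr1"]
        for name in ("query.bed", "reference.bed"):
            fs = ic.read_features(tmp_path / name, "bed", space)
            ic.write_bed(
                ic.FeatureSet({c: fs.on(c) for c in keep}), tmp_path / name
            )
        with open(tmp_path / "genome.sizes", "w") as fh:
            for c in keep:
                fh.write(f"{c}\t{space.length(c)}\n")
        partial = ic.run(cfg)

        for c in keep:
            a = full.results["query_vs_reference"][c]["relative"]
            b = partial.results["query_vs_reference"][c]["relative"]
            assert a == b

    def test_direction_asymmetry_in_results(self, tmp_path):
        write_dataset(tmp_path, "asymmetric")
        report = ic.run(base_config(tmp_path, tests=("relative", "jaccard")))
        fwd = report.results["query_vs_reference"]["genome"]
        rev = report.results["reference_vs_query"]["genome"]
        # Jaccard is symmetric in the two sets; relative distance is not
        assert fwd["jaccard"].jaccard == rev["jaccard"].jaccard
        assert fwd["relative"].ks_p != rev["relative"].ks_p

    def test_mask_restriction_runs_on_pseudochromosomes(self, tmp_path):
        write_dataset(tmp_path, "independent", n_reference=300, n_query=300)
        mask = ic.FeatureSet(
            {"chr1": np.array([[0, 400_000]]), "chr2": np.array([[100_000, 700_000]])}
        )
        ic.write_bed(mask, tmp_path / "mask.bed")
        cfg = base_config(tmp_path, mask=str(tmp_path / "mask.bed"),
                          tests=("projection",))
        report = ic.run(cfg)
        scopes = set(report.results["query_vs_reference"])
        assert scopes <= {"chr1:0-400000", "chr2:100000-700000", "genome"}

    def test_empty_mask_fails_before_computation(self, tmp_path):
        write_dataset(tmp_path, "independent", n_reference=20, n_query=20)
        (tmp_path / "mask.bed").write_text("")
        cfg = base_config(tmp_path, mask=str(tmp_path / "mask.bed"))
        with pytest.raises(ValueError, match="mask"):
            ic.run(cfg)

    def test_skipped_chromosome_is_reported_not_fatal(self, tmp_path):
        spec = write_dataset(tmp_path, "independent", n_reference=30, n_query=30)
        # reference only on chr1: other chromosomes must be skipped for
        # distance tests but still appear in the skip log
        space = ic.GenomeSpace(spec.chrom_lengths)
        ref = ic.read_features(tmp_path / "reference.bed", "bed", space)
        ic.write_bed(
            ic.FeatureSet({"chr1": ref.on("chr1")}), tmp_path / "reference.bed"
        )
        report = ic.run(base_config(tmp_path, tests=("relative",),
                                    both_directions=False))
        skipped_scopes = {s["scope"] for s in report.skipped}
        assert {"chr2", "chr3", "chr4"} <= skipped_scopes
        assert "chr1" in report.results["query_vs_reference"]


class TestReportSerialization:
    def test_json_round_trips_nested_structure(self, tmp_path):
        write_dataset(tmp_path, "independent", n_reference=40, n_query=40)
        report = ic.run(base_config(tmp_path, tests=("projection", "jaccard")))
        loaded = json.loads((tmp_path / "out" / "report.json").read_text())
        assert loaded == report.to_dict()
        assert "meta" in loaded and "skipped" in loaded

    def test_tsv_has_one_row_per_direction_scope_test(self, tmp_path):
        write_dataset(tmp_path, "independent", n_reference=40, n_query=40)
        report = ic.run(base_config(tmp_path, tests=("projection",)))
        frame = report.to_frame()
        n_rows = sum(len(tests) for scopes in report.results.values()
                     for tests in scopes.values())
        assert len(frame) == n_rows
        assert list(frame["test"].unique()) == ["projection"]

    def test_empty_test_list_rejected_vs_header_only(self, tmp_path):
        report = ic.Report()
        frame = report.to_frame()
        assert len(frame) == 0
        assert "statistic" in frame.columns  # header-only table


class TestConfig:
    def test_ini_round_trip_with_overrides(self, tmp_path):
        ini = tmp_path / "run.ini"
        ini.write_text(
            "[data]\nquery = q.bed\nreference = r.bed\ngenome = g.sizes\n"
            "[tests]\ntests = relative, jaccard\nn_perm = 250\n"
            "[options]\nseed = 7\nedge_mode = drop\nboth_directions = false\n"
        )
        cfg = ic.RunConfig.from_ini(ini, seed=9)
        assert cfg.tests == ("relative", "jaccard")
        assert cfg.n_perm == 250
        assert cfg.seed == 9  # override wins
        assert cfg.edge_mode == "drop"
        assert cfg.both_directions is False

    @pytest.mark.parametrize(
        "bad",
        [dict(tests=("bogus",)), dict(n_perm=10), dict(seed=-1),
         dict(edge_mode="spiral"), dict(alpha=1.5)],
    )
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            ic.RunConfig(**bad)


class TestCli:
    def test_simulate_then_run(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        result = runner.invoke(
            cli_main,
            ["simulate", "--relationship", "coincident", "--seed", "5",
             "--out", str(data)],
        )
        assert result.exit_code == 0, result.output
        assert (data / "truth.json").exists()
        result = runner.invoke(
            cli_main,
            ["run", "--query", str(data / "query.bed"),
             "--reference", str(data / "reference.bed"),
             "--genome", str(data / "genome.sizes"),
             "--tests", "relative", "--n-perm", "150", "--seed", "2",
             "--no-reverse", "--out", str(tmp_path / "res")],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "res" / "report.tsv").exists()
        assert "relative" in result.output


class TestPlots:
    def test_summary_pdf_written_per_scope(self, tmp_path):
        rng = np.random.default_rng(0)
        rel = {"chr1": rng.uniform(0, 0.5, 100), "genome": rng.uniform(0, 0.5, 100)}
        ab = {"chr1": rng.exponential(0.5, 100), "genome": rng.exponential(0.5, 100)}
        out = ic.plot_summary(rel, ab, tmp_path / "plots" / "summary.pdf")
        assert out.exists() and out.stat().st_size > 0
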