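"""Cohort generator determinism, planted-truth recovery and the CLI."""

import json
from collections import Counter

import pytest
from click.testing import CliRunner

from neoprio import (
    SchemaError,
    SimulationConfig,
    Thresholds,
    run_pipeline,
    simulate_cohort,
)
from neoprio.cli import main
from neoprio.config import TIER_LADDER


class TestSimulateCohort:
    def test_seed_determinism_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(SimulationConfig(seed=7, n_variants=6)).write(d1)
        simulate_cohort(SimulationConfig(seed=7, n_variants=6)).write(d2)
        for name in ("metrics.json", "proteome.fasta", "anchors.tsv", "manifest.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seed_differs(self):
        a = simulate_cohort(SimulationConfig(seed=1, n_variants=4))
        b = simulate_cohort(SimulationConfig(seed=2, n_variants=4))
        assert set(a.bundle.variants) != set(b.bundle.variants)

    def test_interior_missense_yields_38_peptides_per_transcript(self):
        cfg = SimulationConfig(
            seed=5, n_variants=10, frameshift_fraction=0.0,
            fraction_anchor=0.0, fraction_poor_binding=0.0,
            fraction_subclonal=0.0, fraction_unexpressed=0.0,
        )
        cohort = simulate_cohort(cfg)
        for entry in cohort.bundle.variants.values():
            for tx in entry.transcripts:
                assert len(tx.peptide_ids) == 38

    def test_planted_unexpressed_count_matches_manifest(self):
        cfg = SimulationConfig(seed=3, n_variants=40, fraction_unexpressed=0.3)
        cohort = simulate_cohort(cfg)
        planted = [v for v in cohort.manifest.values() if v["category"] == "noexpr"]
        assert len(planted) == round(0.3 * 40)
        zero_expr = [
            vid
            for vid, e in cohort.bundle.variants.items()
            if e.gene_expr == 0.0
        ]
        assert sorted(zero_expr) == sorted(
            vid for vid, m in cohort.manifest.items() if m["category"] == "noexpr"
        )

    def test_wt_proteins_present_in_proteome(self, small_cohort):
        for entry in small_cohort.bundle.variants.values():
            for tx in entry.transcripts:
                assert tx.protein_seq in small_cohort.proteome

    def test_overfull_fractions_rejected(self):
        with pytest.raises(SchemaError, match="fractions"):
            simulate_cohort(
                SimulationConfig(
                    n_variants=10, fraction_subclonal=0.6, fraction_unexpressed=0.6
                )
            )


class TestRunPipeline:
    def test_deterministic_report(self, small_cohort):
        rows1, _ = run_pipeline(small_cohort.bundle, small_cohort.proteome, small_cohort.anchors)
        rows2, _ = run_pipeline(small_cohort.bundle, small_cohort.proteome, small_cohort.anchors)
        assert rows1 == rows2

    def test_rows_ordered_by_tier_then_ic50(self, small_cohort):
        rows, _ = run_pipeline(small_cohort.bundle, small_cohort.proteome, small_cohort.anchors)
        keys = [(TIER_LADDER.index(r.tier), r.ic50_mt) for r in rows]
        assert keys == sorted(keys)

    def test_planted_tiers_recovered(self, small_cohort):
        rows, _ = run_pipeline(small_cohort.bundle, small_cohort.proteome, small_cohort.anchors)
        by_id = {r.variant_id: r for r in rows}
        for vid, planted in small_cohort.manifest.items():
            assert by_id[vid].tier == planted["planted_tier"], vid

    def test_single_all_passing_variant(self):
        cohort = simulate_cohort(
            SimulationConfig(
                seed=9, n_variants=1, fraction_subclonal=0.0, fraction_unexpressed=0.0,
                fraction_anchor=0.0, fraction_poor_binding=0.0, frameshift_fraction=0.0,
            )
        )
        rows, session = run_pipeline(cohort.bundle, cohort.proteome, cohort.anchors)
        assert rows[0].tier == "Pass"
        assert rows[0].num_passing_peptides >= 1
        assert session.tally() == {"Accept": 0, "Reject": 0, "Review": 0}

    def test_best_wt_peptides_reference_match_by_construction(self, small_cohort):
        from neoprio import reference_match

        for entry in small_cohort.bundle.variants.values():
            for pep in entry.peptides.values():
                if pep.wt_seq is not None:
                    assert reference_match(pep.wt_seq, small_cohort.proteome).matched

    def test_fresh_session_all_pending(self, small_cohort):
        rows, session = run_pipeline(
            small_cohort.bundle, small_cohort.proteome, small_cohort.anchors
        )
        assert all(r.evaluation == "Pending" for r in rows)
        assert set(session.states) == {r.variant_id for r in rows}

    def test_stricter_threshold_demotes(self, small_cohort):
        strict = Thresholds(binding_threshold_nm=10.0)
        rows, _ = run_pipeline(
            small_cohort.bundle, small_cohort.proteome, small_cohort.anchors, strict
        )
        assert all(r.tier == "Poor" for r in rows)


class TestCli:
    def test_simulate_run_session_roundtrip(self, tmp_path):
        runner = CliRunner()
        out_dir = tmp_path / "fix"
        result = runner.invoke(
            main, ["simulate", "--seed", "4", "--n-variants", "5", "--out-dir", str(out_dir)]
        )
        assert result.exit_code == 0, result.output
        agg = tmp_path / "agg.tsv"
        result = runner.invoke(
            main,
            [
                "run",
                "--metrics", str(out_dir / "metrics.json"),
                "--proteome", str(out_dir / "proteome.fasta"),
                "--anchors", str(out_dir / "anchors.tsv"),
                "--out", str(agg),
            ],
        )
        assert result.exit_code == 0, result.output
        assert agg.exists()
        with open(out_dir / "manifest.json") as fh:
            manifest = json.load(fh)
        vid = next(iter(manifest["variants"]))
        result = runner.invoke(
            main, ["session", "--aggregate", str(agg), "--set", f"{vid}=Accept"]
        )
        assert result.exit_code == 0, result.output
        assert "Accept=1" in result.output

    def test_tier_override_changes_tiers(self, tmp_path):
        runner = CliRunner()
        out_dir = tmp_path / "fix"
        runner.invoke(main, ["simulate", "--seed", "4", "--n-variants", "4", "--out-dir", str(out_dir)])
        agg = tmp_path / "agg.tsv"
        result = runner.invoke(
            main,
            [
                "tier",
                "--metrics", str(out_dir / "metrics.json"),
                "--proteome", str(out_dir / "proteome.fasta"),
                "--anchors", str(out_dir / "anchors.tsv"),
                "--out", str(agg),
                "--binding-threshold", "5",
            ],
        )
        assert result.exit_code == 0, result.output
        tiers = Counter(
            line.split("\t")[18] for line in agg.read_text().splitlines()[1:]
        )
        assert set(tiers) == {"Poor"}

    def test_report_drilldown(self, tmp_path):
        runner = CliRunner()
        out_dir = tmp_path / "fix"
        runner.invoke(main, ["simulate", "--seed", "4", "--n-variants", "2", "--out-dir", str(out_dir)])
        with open(out_dir / "manifest.json") as fh:
            vid = next(iter(json.load(fh)["variants"]))
        result = runner.invoke(
            main,
            [
                "report",
                "--metrics", str(out_dir / "metrics.json"),
                "--anchors", str(out_dir / "anchors.tsv"),
                "--variant", vid,
            ],
        )
        assert result.exit_code == 0, result.output
        assert "transcript set" in result.output
        assert "anchors:" in result.output

    def test_convert_custom(self, tmp_path):
        src = tmp_path / "cand.tsv"
        src.write_text("variant\tpep\tscore\nv1\tAAA\t1\nv1\tBBB\t2\nv2\tCCC\t3\n")
        out = tmp_path / "grouped.tsv"
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["convert", "--format", "custom", "--in", str(src), "--out", str(out),
             "--group-by", "variant", "--sort-by", "score"],
        )
        assert result.exit_code == 0, result.output
        assert "2 groups" in result.output
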