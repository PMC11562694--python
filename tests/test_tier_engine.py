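"""Derived features, peptide screening, best-peptide selection and tiering."""

import itertools
import random

import pytest

from neoprio import (
    BindingSummary,
    Candidate,
    Proteome,
    SchemaError,
    SpecError,
    Thresholds,
    VariantSummary,
    allele_expression,
    assign_tier,
    attach_supplemental,
    clonality_call,
    count_passing,
    flag_genes_of_interest,
    flag_problematic,
    reference_match,
    select_best_peptide,
    tier_from_failures,
)
from neoprio.io_formats import SupplementalRecord
from neoprio.tier_engine import (
    FAIL_ANCHOR,
    FAIL_BINDING,
    FAIL_LOWEXPR,
    FAIL_NOEXPR,
    FAIL_SUBCLONAL,
    FAIL_TSL,
    ProblematicSpec,
)
from .test_io_formats import make_row


class TestAlleleExpression:
    @pytest.mark.parametrize("expr,vaf,expected", [(10, 0.4, 4.0), (7, 0, 0.0), (0, 1, 0.0)])
    def test_product(self, expr, vaf, expected):
        assert allele_expression(expr, vaf) == expected


class TestClonality:
    def test_below_half_of_clonal_estimate_is_subclonal(self):
        assert clonality_call(0.24, 0.5, 0.5) == "subclonal"

    def test_boundary_inclusive_on_clonal_side(self):
        assert clonality_call(0.25, 0.5, 0.5) == "clonal"

    def test_at_clonal_estimate(self):
        assert clonality_call(0.5, 0.5, 0.5) == "clonal"


class TestReferenceMatch:
    PROTEOME = Proteome({"recA": "MKLVNQWERTYACDEFGHIK", "recB": "PPPPPPPPPPPP"})

    def test_verbatim_substring_found_with_coordinates(self):
        res = reference_match("QWERTY", self.PROTEOME)
        assert res.matched and res.hits == [("recA", 6)]

    def test_single_mismatch_not_matched_in_full_mode(self):
        # exhaustively verify no window of any record equals the query
        query = "QWERTZ"
        for seq in self.PROTEOME.records.values():
            for i in range(len(seq) - len(query) + 1):
                assert seq[i : i + len(query)] != query
        assert not reference_match(query, self.PROTEOME).matched

    def test_wt_peptides_cut_from_proteome_always_match(self):
        rng = random.Random(41)
        seq = self.PROTEOME.records["recA"]
        for _ in range(20):
            ln = rng.randint(8, 11)
            start = rng.randint(0, len(seq) - ln)
            assert reference_match(seq[start : start + ln], self.PROTEOME).matched

    def test_kmer_mode_flags_shared_kmer(self):
        # peptide differs from recA only outside its first 8-mer
        pep = "MKLVNQWE" + "WWW"
        assert reference_match(pep, self.PROTEOME, mode="kmer", m=8).matched
        assert not reference_match(pep, self.PROTEOME, mode="full").matched

    def test_kmer_longer_than_peptide_rejected(self):
        with pytest.raises(SchemaError):
            reference_match("SHORT", self.PROTEOME, mode="kmer", m=8)


class TestProblematicPositions:
    def test_residue_token_scans_whole_peptide(self):
        assert flag_problematic("ACDC", ProblematicSpec.parse("C")) == [2, 4]

    def test_positional_token(self):
        assert flag_problematic("CLDEK", ProblematicSpec.parse("C@1")) == [1]
        assert flag_problematic("KLCDE", ProblematicSpec.parse("C@1")) == []

    def test_empty_spec_flags_nothing(self):
        assert flag_problematic("CCCC", ProblematicSpec(())) == []

    def test_mixed_tokens_sorted_ascending(self):
        assert flag_problematic("MCDCM", ProblematicSpec.parse("C,M@1")) == [1, 2, 4]

    def test_malformed_token_rejected(self):
        with pytest.raises(SpecError, match="B@x"):
            flag_problematic("ACDC", ProblematicSpec.parse("B@x"))


def cand(pid, ic50, verdict="keep", pct=None, seq=None, allele="HLA-A*02:01"):
    return Candidate(
        peptide_id=pid,
        allele=allele,
        mt_seq=seq or f"PEPTIDE{pid.upper()}",
        summary=BindingSummary(pid, allele, ic50, ic50, median_percentile_mt=pct),
        anchor_verdict=verdict,
    )


class TestSelectBestPeptide:
    def test_lower_ic50_wins_among_passing(self, thresholds):
        best = select_best_peptide([cand("a", 300), cand("b", 100)], thresholds)
        assert best.peptide_id == "b"

    def test_keep_beats_deprioritized_despite_higher_ic50(self, thresholds):
        best = select_best_peptide(
            [cand("a", 50, "deprioritize"), cand("b", 400, "keep")], thresholds
        )
        assert best.peptide_id == "b"

    def test_passing_beats_failing_regardless_of_verdict(self, thresholds):
        best = select_best_peptide(
            [cand("a", 5000, "keep"), cand("b", 499, "deprioritize")], thresholds
        )
        assert best.peptide_id == "b"

    def test_deterministic_under_permutation(self, thresholds):
        rng = random.Random(55)
        cands = [
            cand(f"p{i}", rng.choice([100.0, 250.0, 900.0]),
                 rng.choice(["keep", "not_applicable", "deprioritize"]),
                 pct=rng.choice([None, 1.0, 5.0]))
            for i in range(12)
        ]
        winner = select_best_peptide(cands, thresholds)
        for _ in range(10):
            rng.shuffle(cands)
            assert select_best_peptide(cands, thresholds) == winner

    def test_empty_rejected(self, thresholds):
        with pytest.raises(SchemaError):
            select_best_peptide([], thresholds)


ALL_FAILURES = [FAIL_BINDING, FAIL_ANCHOR, FAIL_SUBCLONAL, FAIL_LOWEXPR, FAIL_NOEXPR, FAIL_TSL]


class TestTierLadder:
    def test_no_failures_is_pass(self):
        assert tier_from_failures([]) == "Pass"

    @pytest.mark.parametrize(
        "failure,tier",
        [
            (FAIL_ANCHOR, "Anchor"),
            (FAIL_SUBCLONAL, "Subclonal"),
            (FAIL_LOWEXPR, "LowExpr"),
            (FAIL_NOEXPR, "NoExpr"),
            (FAIL_BINDING, "Poor"),
            (FAIL_TSL, "Poor"),
        ],
    )
    def test_single_failures(self, failure, tier):
        assert tier_from_failures([failure]) == tier

    def test_exhaustive_truth_table(self):
        """Every subset of failing criteria maps to exactly the documented tier."""
        for r in range(len(ALL_FAILURES) + 1):
            for subset in itertools.combinations(ALL_FAILURES, r):
                tier = tier_from_failures(subset)
                if not subset:
                    assert tier == "Pass"
                elif FAIL_BINDING in subset or len(subset) >= 2 or subset == (FAIL_TSL,):
                    assert tier == "Poor"
                else:
                    assert tier in ("Anchor", "Subclonal", "LowExpr", "NoExpr")

    def _summary(self, ic50=100.0, allele_expr=10.0, tsl=1, clonality="clonal", verdict="keep"):
        return VariantSummary(
            variant_id="v1",
            best=cand("p1", ic50, verdict),
            allele_expr=allele_expr,
            tsl=tsl,
            clonality=clonality,
            anchor_verdict=verdict,
        )

    def test_assign_tier_populates_failing_criteria(self, thresholds):
        vs = self._summary(ic50=900.0, clonality="subclonal")
        assert assign_tier(vs, thresholds) == "Poor"
        assert set(vs.failing_criteria) == {FAIL_BINDING, FAIL_SUBCLONAL}

    def test_monotone_in_ic50(self, thresholds):
        """Improving binding affinity never worsens the tier."""
        from neoprio.config import TIER_LADDER

        for expr in (0.0, 0.5, 10.0):
            for clon in ("clonal", "subclonal"):
                for verdict in ("keep", "deprioritize"):
                    tiers = []
                    for ic50 in (2000.0, 500.0, 50.0):
                        vs = self._summary(ic50=ic50, allele_expr=expr, clonality=clon, verdict=verdict)
                        tiers.append(TIER_LADDER.index(assign_tier(vs, thresholds)))
                    assert tiers == sorted(tiers, reverse=True)

    def test_monotone_in_allele_expr(self, thresholds):
        from neoprio.config import TIER_LADDER

        for ic50 in (100.0, 2000.0):
            tiers = []
            for expr in (0.0, 0.5, 10.0):
                vs = self._summary(ic50=ic50, allele_expr=expr)
                tiers.append(TIER_LADDER.index(assign_tier(vs, thresholds)))
            assert tiers == sorted(tiers, reverse=True)


class TestCountPassing:
    def _summaries(self, medians):
        return {
            pid: {
                allele: BindingSummary(pid, allele, m, m)
                for allele, m in per_allele.items()
            }
            for pid, per_allele in medians.items()
        }

    def test_counts_peptides_passing_on_any_allele(self, thresholds):
        summaries = self._summaries(
            {
                "p1": {"A1": 100.0, "A2": 9000.0},
                "p2": {"A1": 9000.0, "A2": 9000.0},
                "p3": {"A1": 450.0, "A2": 450.0},
            }
        )
        txs = {"t1": ("p1", "p2"), "t2": ("p2",), "t3": ("p3",)}
        assert count_passing(summaries, txs, thresholds) == (2, 2)

    def test_zero_passing(self, thresholds):
        summaries = self._summaries({"p1": {"A1": 9000.0}})
        assert count_passing(summaries, {"t1": ("p1",)}, thresholds) == (0, 0)

    def test_matches_brute_force_on_random_fixture(self, thresholds):
        rng = random.Random(71)
        for _ in range(30):
            pids = [f"p{i}" for i in range(rng.randint(1, 10))]
            alleles = [f"A{i}" for i in range(rng.randint(1, 4))]
            medians = {
                pid: {a: rng.choice([50.0, 499.0, 501.0, 30000.0]) for a in alleles}
                for pid in pids
            }
            txs = {
                f"t{i}": tuple(rng.sample(pids, rng.randint(0, len(pids))))
                for i in range(rng.randint(1, 5))
            }
            # independent double loop
            passing = set()
            for pid in pids:
                for a in alleles:
                    if medians[pid][a] <= 500.0:
                        passing.add(pid)
            n_tx = sum(1 for t in txs.values() if any(p in passing for p in t))
            assert count_passing(self._summaries(medians), txs, thresholds) == (
                len(passing),
                n_tx,
            )


class TestRowAnnotations:
    def test_gene_of_interest_exact_case_sensitive(self):
        rows = [make_row(), make_row("chr2-1-A-G", gene="kras")]
        rows[1].gene = "kras"
        flag_genes_of_interest(rows, {"TP53", "KRAS"})
        assert rows[0].gene_of_interest is True
        assert rows[1].gene_of_interest is False

    def test_empty_gene_set_flags_nothing(self):
        rows = [make_row()]
        flag_genes_of_interest(rows, set())
        assert not rows[0].gene_of_interest

    def test_supplemental_left_join(self):
        rows = [make_row(), make_row("chr2-1-A-G")]
        supp = {"chr1-100-A-T": SupplementalRecord(1234.5, 3.25)}
        tier_before = [r.tier for r in rows]
        attach_supplemental(rows, supp)
        assert rows[0].extra["IC50 MT (Class II)"] == "1234.5"
        assert rows[1].extra["IC50 MT (Class II)"] == "NA"
        assert [r.tier for r in rows] == tier_before  # rescue is a user decision

    def test_supplemental_only_variant_warns(self):
        rows = [make_row()]
        supp = {"chr9-9-G-C": SupplementalRecord(10.0, 0.5)}
        with pytest.warns(UserWarning, match="chr9-9-G-C"):
            attach_supplemental(rows, supp)
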