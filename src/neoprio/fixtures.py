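"""Seeded synthetic cohorts and the end-to-end prioritization pipeline.

The generator emulates what an upstream variant-calling + epitope-prediction
pipeline would hand to the prioritization engine: per-variant transcript
protein context, DNA/RNA evidence, a reference proteome containing every
wild-type protein, allele/length-specific anchor profiles, and mock
per-algorithm binding/elution/immunogenicity scores.  Mock scores are
seeded hash functions of (peptide, allele, algorithm) — reproducible
without model weights and deliberately non-biological.

Each variant is planted with exactly one failure mode (or none), recorded
in a manifest, so the pipeline's tier assignments can be checked against
ground truth.
"""

from __future__ import annotations

import hashlib
import json
import math
import random
from dataclasses import asdict, dataclass, field

from .anchor_engine import (
    AnchorProfile,
    AnchorProfileSet,
    anchor_positions,
    classify_scenario,
    write_anchor_profiles,
)
from .config import Thresholds
from .errors import IntegrityError, SchemaError
from .evaluation_session import SessionState
from .io_formats import (
    AggregateReportRow,
    BindingScore,
    MetricsBundle,
    PeptideEntry,
    Proteome,
    TranscriptEntry,
    VariantEntry,
    write_metrics,
    write_proteome,
)
from .peptide_engine import (
    PeptidePair,
    TranscriptSpec,
    VariantSpec,
    generate_candidates,
    group_transcript_sets,
)
from .prediction_core import (
    CLASS_I_BINDING,
    CLASS_I_ELUTION,
    CLASS_I_IMMUNOGENICITY,
    passes_binding_filter,
    summarize_binding,
)
from .tier_engine import (
    Candidate,
    ProblematicSpec,
    VariantSummary,
    assign_tier,
    clonality_call,
    count_passing,
    flag_genes_of_interest,
    flag_problematic,
    reference_match,
    select_best_peptide,
    tier_rank,
)

HLA_CLASS_I_ALLELES = (
    "HLA-A*01:01",
    "HLA-A*02:01",
    "HLA-B*07:02",
    "HLA-B*08:01",
    "HLA-C*07:01",
    "HLA-C*07:02",
)

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# planted failure categories and the tier each should earn when it is the
# only failing criterion
PLANT_TIERS = {
    "pass": "Pass",
    "noexpr": "NoExpr",
    "subclonal": "Subclonal",
    "anchor": "Anchor",
    "poor": "Poor",
}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults follow the canonical class I setting: peptide lengths 8-11,
    six patient alleles, and a clonal VAF around 0.5 with subclonal
    variants below half of it.
    """

    seed: int = 0
    n_variants: int = 20
    n_transcripts_per_variant: int = 2
    protein_length_range: tuple[int, int] = (45, 60)
    lengths: tuple[int, ...] = (8, 9, 10, 11)
    n_class_i_alleles: int = 6
    fraction_subclonal: float = 0.2
    fraction_unexpressed: float = 0.1
    fraction_anchor: float = 0.1
    fraction_poor_binding: float = 0.1
    frameshift_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "fraction_subclonal",
            "fraction_unexpressed",
            "fraction_anchor",
            "fraction_poor_binding",
            "frameshift_fraction",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SchemaError(f"{name} must be in [0, 1]")
        if self.n_variants < 1:
            raise SchemaError("n_variants must be >= 1")
        if not (1 <= self.n_class_i_alleles <= len(HLA_CLASS_I_ALLELES)):
            raise SchemaError(
                f"n_class_i_alleles must be in [1, {len(HLA_CLASS_I_ALLELES)}]"
            )
        if 9 not in self.lengths:
            raise SchemaError("cohort planting requires 9-mer candidates (9 in lengths)")
        lo, hi = self.protein_length_range
        if lo < 2 * max(self.lengths) or hi < lo:
            raise SchemaError(
                "protein_length_range must allow interior mutations "
                f"(min {2 * max(self.lengths)})"
            )


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    bundle: MetricsBundle
    proteome: Proteome
    anchors: AnchorProfileSet
    #: variant_id -> {"category", "planted_tier", "designated_peptide", "designated_allele"}
    manifest: dict[str, dict] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_metrics(self.bundle, os.path.join(out_dir, "metrics.json"))
        write_proteome(self.proteome, os.path.join(out_dir, "proteome.fasta"))
        write_anchor_profiles(self.anchors, os.path.join(out_dir, "anchors.tsv"))
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(
                {"config": asdict(self.config), "variants": self.manifest},
                fh,
                indent=1,
            )
            fh.write("\n")


# ---------------------------------------------------------------------------
# mock scorers
# ---------------------------------------------------------------------------

def _hash_rng(seed: int, *parts: str) -> random.Random:
    digest = hashlib.sha256("|".join((str(seed),) + parts).encode()).digest()
    return random.Random(int.from_bytes(digest[:8], "big"))


def mock_binding_score(
    seed: int, peptide: str, allele: str, algorithm: str, lo: float = 1.0, hi: float = 50000.0
) -> BindingScore:
    """Log-uniform IC50 in [lo, hi] nM with a monotone percentile map,
    deterministic in (seed, peptide, allele, algorithm)."""
    rng = _hash_rng(seed, "binding", peptide, allele, algorithm)
    ic50 = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    percentile = min(100.0, max(0.0, 100.0 * math.log(ic50) / math.log(50000.0)))
    return BindingScore(ic50=round(ic50, 3), percentile=round(percentile, 2))


def mock_presentation_score(seed: int, peptide: str, allele: str, algorithm: str) -> float:
    rng = _hash_rng(seed, "presentation", peptide, allele, algorithm)
    return round(rng.random(), 3)


def _score_block(
    seed: int, peptide: str, alleles, strong_allele: str | None, lo_strong, hi_strong, lo_weak, hi_weak
) -> dict[str, dict[str, BindingScore]]:
    block: dict[str, dict[str, BindingScore]] = {}
    for allele in alleles:
        if allele == strong_allele:
            lo, hi = lo_strong, hi_strong
        else:
            lo, hi = lo_weak, hi_weak
        block[allele] = {
            alg: mock_binding_score(seed, peptide, allele, alg, lo, hi)
            for alg in CLASS_I_BINDING
        }
    return block


def _random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_RESIDUES) for _ in range(length))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def default_anchor_profiles(alleles, lengths) -> AnchorProfileSet:
    """Two-anchor profiles (positions 2 and C-terminus carry 0.45 each)
    for every allele/length combination."""
    profiles = AnchorProfileSet()
    for allele in alleles:
        for length in sorted(set(lengths)):
            rest = 0.10 / (length - 2)
            probs = tuple(
                0.45 if i in (2, length) else rest for i in range(1, length + 1)
            )
            profiles.add(AnchorProfile(allele=allele, length=length, probabilities=probs))
    return profiles


def _assign_categories(rng: random.Random, config: SimulationConfig) -> list[str]:
    n = config.n_variants
    counts = {
        "noexpr": round(config.fraction_unexpressed * n),
        "subclonal": round(config.fraction_subclonal * n),
        "anchor": round(config.fraction_anchor * n),
        "poor": round(config.fraction_poor_binding * n),
    }
    total_planted = sum(counts.values())
    if total_planted > n:
        raise SchemaError("planted fractions sum to more than 1")
    if counts["subclonal"] > 0 and counts["subclonal"] == n:
        raise SchemaError("an all-subclonal cohort has no clonal VAF anchor point")
    categories = (
        ["noexpr"] * counts["noexpr"]
        + ["subclonal"] * counts["subclonal"]
        + ["anchor"] * counts["anchor"]
        + ["poor"] * counts["poor"]
        + ["pass"] * (n - total_planted)
    )
    rng.shuffle(categories)
    return categories


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a fully synthetic, seed-deterministic cohort.

    Every variant carries at most one planted failing criterion; the
    designated best peptide (a 9-mer) is made the unique good binder on one
    allele for non-poor variants, with its mutation placed on an anchor
    position (and its WT made a strong binder) only for anchor-category
    variants.  Wild-type proteins all enter the proteome.
    """
    rng = random.Random(config.seed)
    alleles = HLA_CLASS_I_ALLELES[: config.n_class_i_alleles]
    categories = _assign_categories(rng, config)

    bundle = MetricsBundle(hla_alleles=alleles)
    proteome_records: dict[str, str] = {}
    manifest: dict[str, dict] = {}
    max_len = max(config.lengths)

    for i, category in enumerate(categories):
        gene = f"GENE{i + 1}"
        chrom = f"chr{(i % 22) + 1}"
        gpos = rng.randint(1_000_000, 50_000_000)
        ref_nt, alt_nt = rng.sample("ACGT", 2)
        vid = f"{chrom}-{gpos}-{ref_nt}-{alt_nt}"

        is_frameshift = category != "anchor" and rng.random() < config.frameshift_fraction
        lo, hi = config.protein_length_range
        plen = rng.randint(lo, hi)
        ppos = rng.randint(max_len, plen - max_len + 1)
        protein = _random_protein(rng, plen)
        ref_aa = protein[ppos - 1]

        novel_tail = None
        if is_frameshift:
            variant_class = "frameshift"
            alt_aa = ""
            # stop codon after the novel run; residues past it must never appear
            novel_tail = _random_protein(rng, rng.randint(12, 18)) + "*" + _random_protein(rng, 3)
            aa_change = f"{ref_aa}{ppos}fs"
        else:
            variant_class = "missense"
            alt_aa = rng.choice([r for r in _RESIDUES if r != ref_aa])
            aa_change = f"{ref_aa}{ppos}{alt_aa}"

        # DNA / RNA evidence per planted category
        if category == "subclonal":
            dna_vaf = round(rng.uniform(0.05, 0.19), 2)
        else:
            dna_vaf = round(rng.uniform(0.40, 0.50), 2)
        rna_vaf = round(rng.uniform(0.20, 0.80), 2)
        gene_expr = 0.0 if category == "noexpr" else round(rng.uniform(10.0, 100.0), 3)
        rna_depth = rng.randint(50, 300)

        variant = VariantSpec(
            variant_id=vid,
            variant_class=variant_class,
            protein_pos=ppos,
            ref_aa=ref_aa if not is_frameshift else ref_aa,
            alt_aa=alt_aa,
            dna_vaf=dna_vaf,
            rna_vaf=rna_vaf,
            rna_depth=rna_depth,
            gene=gene,
            gene_expr=gene_expr,
        )

        transcripts: list[TranscriptSpec] = []
        for j in range(config.n_transcripts_per_variant):
            tid = f"T{i:04d}.{j + 1}"
            if j == 0 or rng.random() < 0.5:
                seq = protein
            else:
                # alternative isoform: same mutation context, different sequence
                seq = list(_random_protein(rng, plen))
                seq[ppos - 1] = ref_aa
                seq = "".join(seq)
            transcripts.append(
                TranscriptSpec(
                    transcript_id=tid,
                    protein_seq=seq,
                    tsl=1,
                    biotype="protein_coding",
                    expression=round(rng.uniform(1.0, 50.0), 3),
                )
            )
            proteome_records.setdefault(f"{gene}|{tid}", seq)

        per_tx = generate_candidates(variant, transcripts, config.lengths, novel_tail)
        tx_sets = group_transcript_sets(per_tx)

        # stable peptide ids keyed by MT sequence, in canonical order
        pid_by_seq: dict[str, str] = {}
        pair_by_seq: dict[str, PeptidePair] = {}
        for tx in sorted(transcripts, key=lambda t: t.transcript_id):
            for pair in per_tx[tx.transcript_id]:
                if pair.mt_seq not in pid_by_seq:
                    pid_by_seq[pair.mt_seq] = f"p{i}.{len(pid_by_seq) + 1}"
                    pair_by_seq[pair.mt_seq] = pair

        # the designated best 9-mer from the first transcript: mutation on an
        # anchor position (2) for anchor-category variants, off-anchor (5)
        # otherwise
        designated_start = ppos - 1 if category == "anchor" else ppos - 4
        designated_seq = None
        for pair in per_tx[transcripts[0].transcript_id]:
            if pair.length == 9 and pair.start == designated_start:
                designated_seq = pair.mt_seq
                break
        if designated_seq is None:  # pragma: no cover - interior placement guarantees it
            raise AssertionError("designated 9-mer not generated")
        designated_pid = pid_by_seq[designated_seq]
        designated_allele = alleles[rng.randrange(len(alleles))]

        set_of_tx = {
            tid: ts.set_id for ts in tx_sets for tid in ts.transcript_ids
        }
        entry = VariantEntry(
            variant_id=vid,
            gene=gene,
            variant_class=variant_class,
            protein_pos=ppos,
            ref_aa=variant.ref_aa,
            alt_aa=variant.alt_aa,
            aa_change=aa_change,
            dna_vaf=dna_vaf,
            rna_vaf=rna_vaf,
            rna_depth=rna_depth,
            gene_expr=gene_expr,
            novel_tail=novel_tail,
        )
        for tx in transcripts:
            entry.transcripts.append(
                TranscriptEntry(
                    transcript_id=tx.transcript_id,
                    tsl=tx.tsl,
                    biotype=tx.biotype,
                    expression=tx.expression,
                    peptide_ids=tuple(pid_by_seq[p.mt_seq] for p in per_tx[tx.transcript_id]),
                    transcript_set_id=set_of_tx[tx.transcript_id],
                    protein_seq=tx.protein_seq,
                )
            )
        for seq, pid in pid_by_seq.items():
            pair = pair_by_seq[seq]
            strong = designated_allele if (category != "poor" and pid == designated_pid) else None
            mt_binding = _score_block(
                config.seed, seq, alleles, strong, 20.0, 300.0, 1500.0, 50000.0
            )
            wt_binding: dict[str, dict[str, BindingScore]] = {}
            if pair.wt_seq is not None:
                wt_strong = (
                    designated_allele
                    if (category == "anchor" and pid == designated_pid)
                    else None
                )
                wt_binding = _score_block(
                    config.seed, pair.wt_seq, alleles, wt_strong, 50.0, 300.0, 1500.0, 40000.0
                )
            entry.peptides[pid] = PeptideEntry(
                peptide_id=pid,
                mt_seq=seq,
                wt_seq=pair.wt_seq,
                mutated_positions=pair.mutated_positions,
                mt_binding=mt_binding,
                wt_binding=wt_binding,
                elution={
                    allele: {
                        alg: mock_presentation_score(config.seed, seq, allele, alg)
                        for alg in CLASS_I_ELUTION
                    }
                    for allele in alleles
                },
                immunogenicity={
                    allele: {
                        alg: mock_presentation_score(config.seed, seq, allele, alg)
                        for alg in CLASS_I_IMMUNOGENICITY
                    }
                    for allele in alleles
                },
            )
        bundle.variants[vid] = entry
        manifest[vid] = {
            "category": category,
            "planted_tier": PLANT_TIERS[category],
            "designated_peptide": designated_pid,
            "designated_allele": designated_allele,
            "frameshift": is_frameshift,
        }

    # a few decoy proteins so the proteome is not only cohort proteins
    for k in range(3):
        proteome_records[f"DECOY{k + 1}"] = _random_protein(rng, rng.randint(80, 120))

    bundle.validate()
    cohort = SimulatedCohort(
        config=config,
        bundle=bundle,
        proteome=Proteome(proteome_records),
        anchors=default_anchor_profiles(alleles, config.lengths),
        manifest=manifest,
    )
    return cohort


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    bundle: MetricsBundle,
    proteome: Proteome,
    anchors: AnchorProfileSet,
    thresholds: Thresholds | None = None,
    lengths=(8, 9, 10, 11),
    gene_set: set[str] | None = None,
    problematic: ProblematicSpec | None = None,
) -> tuple[list[AggregateReportRow], SessionState]:
    """Compose peptide enumeration, score aggregation, anchor
    classification and tiering into the aggregate report.

    Rows are ordered by tier (ladder rank), then representative MT IC50,
    then variant id.  Returns the rows and a fresh (all-Pending) session.
    """
    thresholds = thresholds or Thresholds()
    bundle.validate()

    clonal_vaf_estimate = min(
        0.5, max((v.dna_vaf for v in bundle.variants.values()), default=0.5)
    )

    rows: list[AggregateReportRow] = []
    for vid, entry in bundle.variants.items():
        transcripts = []
        for tx in entry.transcripts:
            if tx.protein_seq is None:
                raise IntegrityError(
                    f"variant {vid}: transcript {tx.transcript_id} lacks a protein "
                    f"sequence; cannot re-enumerate peptides"
                )
            transcripts.append(
                TranscriptSpec(
                    transcript_id=tx.transcript_id,
                    protein_seq=tx.protein_seq,
                    tsl=tx.tsl,
                    biotype=tx.biotype,
                    expression=tx.expression,
                )
            )
        variant = VariantSpec(
            variant_id=vid,
            variant_class=entry.variant_class,
            protein_pos=entry.protein_pos,
            ref_aa=entry.ref_aa,
            alt_aa=entry.alt_aa,
            dna_vaf=entry.dna_vaf,
            rna_vaf=entry.rna_vaf,
            rna_depth=entry.rna_depth,
            gene=entry.gene,
            gene_expr=entry.gene_expr,
        )
        per_tx = generate_candidates(variant, transcripts, lengths, entry.novel_tail)
        pair_by_seq: dict[str, PeptidePair] = {}
        for pairs in per_tx.values():
            for pair in pairs:
                pair_by_seq.setdefault(pair.mt_seq, pair)

        # aggregate per (peptide, allele)
        summaries: dict[str, dict[str, object]] = {}
        candidates: list[Candidate] = []
        for pid, pep in entry.peptides.items():
            pair = pair_by_seq.get(pep.mt_seq)
            if pair is None:
                raise IntegrityError(
                    f"variant {vid}: peptide {pid} ({pep.mt_seq}) is not producible "
                    f"from the variant's transcripts"
                )
            summaries[pid] = {}
            for allele, mt_scores in pep.mt_binding.items():
                summary = summarize_binding(
                    pid, allele, mt_scores, pep.wt_binding.get(allele)
                )
                summaries[pid][allele] = summary
                profile = anchors.get(allele, pair.length)
                if profile is None:
                    verdict = "not_applicable"
                else:
                    anchor_set = anchor_positions(profile, thresholds.mass_threshold)
                    verdict = classify_scenario(
                        pair,
                        anchor_set,
                        summary.median_ic50_wt,
                        thresholds.binding_threshold_nm,
                    ).verdict
                candidates.append(
                    Candidate(
                        peptide_id=pid,
                        allele=allele,
                        mt_seq=pep.mt_seq,
                        summary=summary,
                        anchor_verdict=verdict,
                    )
                )
        best = select_best_peptide(candidates, thresholds)
        best_pair = pair_by_seq[best.mt_seq]

        n_pep, n_tx = count_passing(
            summaries,
            {tx.transcript_id: tx.peptide_ids for tx in entry.transcripts},
            thresholds,
        )

        carriers = [
            tx for tx in entry.transcripts if best.peptide_id in tx.peptide_ids
        ]
        carriers.sort(key=lambda tx: (tx.tsl if tx.tsl is not None else 99, tx.transcript_id))
        best_tx = carriers[0] if carriers else entry.transcripts[0]

        allele_expr = round(entry.gene_expr * entry.rna_vaf, 6)
        vsummary = VariantSummary(
            variant_id=vid,
            best=best,
            allele_expr=allele_expr,
            tsl=best_tx.tsl,
            clonality=clonality_call(
                entry.dna_vaf, clonal_vaf_estimate, thresholds.subclonal_fraction
            ),
            anchor_verdict=best.anchor_verdict,
        )
        tier = assign_tier(vsummary, thresholds)

        best_passes = passes_binding_filter(best.summary, thresholds)
        ref = reference_match(
            best.mt_seq, proteome, thresholds.ref_match_mode, thresholds.kmer_size
        )
        prob_pos = (
            tuple(flag_problematic(best.mt_seq, problematic)) if problematic else ()
        )
        rep_ic50 = best.summary.representative_ic50(thresholds)
        rows.append(
            AggregateReportRow(
                variant_id=vid,
                gene=entry.gene,
                aa_change=entry.aa_change,
                pos_in_core=best_pair.mutated_positions,
                best_peptide=best.mt_seq,
                best_transcript=best_tx.transcript_id,
                tsl=best_tx.tsl,
                allele=best.allele,
                ic50_mt=round(rep_ic50, 3),
                percentile_mt=(
                    round(best.summary.median_percentile_mt, 2)
                    if best.summary.median_percentile_mt is not None
                    else None
                ),
                ic50_wt=(
                    round(best.summary.median_ic50_wt, 3)
                    if (best_passes and best.summary.median_ic50_wt is not None)
                    else None
                ),
                num_passing_peptides=n_pep,
                num_passing_transcripts=n_tx,
                rna_expr=round(entry.gene_expr, 3),
                rna_vaf=round(entry.rna_vaf, 2),
                allele_expr=allele_expr,
                rna_depth=entry.rna_depth,
                dna_vaf=round(entry.dna_vaf, 2),
                tier=tier,
                ref_match=ref.matched,
                prob_pos=prob_pos,
            )
        )

    rows.sort(
        key=lambda r: (
            tier_rank(r.tier),
            r.ic50_mt if r.ic50_mt is not None else float("inf"),
            r.variant_id,
        )
    )
    if gene_set is not None:
        flag_genes_of_interest(rows, gene_set)
    return rows, SessionState.from_rows(rows)
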