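"""Variant-level derived features, peptide screening and tier assignment.

The tier of a variant summarizes which prioritization criteria its best
peptide fails: binding affinity, allele expression, transcript support
level, tumor clonality and anchor scenario.  The ladder, best to worst, is
Pass > Anchor > Subclonal > LowExpr > NoExpr > Poor; the named middle tiers
apply when exactly that one criterion fails, while a binding failure, a TSL
failure, or two or more failures of any kind yield Poor.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .config import TIER_LADDER, Thresholds
from .errors import SchemaError, SpecError
from .io_formats import (
    AMINO_ACIDS,
    AggregateReportRow,
    Proteome,
    SupplementalRecord,
    fmt_number,
)
from .prediction_core import BindingSummary, passes_binding_filter

# failure-criterion codes, in ladder order of their single-failure tiers
FAIL_BINDING = "binding"
FAIL_ANCHOR = "anchor"
FAIL_SUBCLONAL = "subclonal"
FAIL_LOWEXPR = "lowexpr"
FAIL_NOEXPR = "noexpr"
FAIL_TSL = "tsl"

_SINGLE_FAILURE_TIERS = {
    FAIL_ANCHOR: "Anchor",
    FAIL_SUBCLONAL: "Subclonal",
    FAIL_LOWEXPR: "LowExpr",
    FAIL_NOEXPR: "NoExpr",
}

TierThresholds = Thresholds  # canonical name lives in neoprio.config


def allele_expression(rna_expr: float, rna_vaf: float) -> float:
    """Expression attributable to the mutant allele: gene TPM x RNA VAF."""
    if rna_expr < 0 or not (0 <= rna_vaf <= 1):
        raise SchemaError("rna_expr must be >= 0 and rna_vaf in [0, 1]")
    return rna_expr * rna_vaf


def clonality_call(
    dna_vaf: float, clonal_vaf_estimate: float = 0.5, subclonal_fraction: float = 0.5
) -> str:
    """"subclonal" when DNA VAF < subclonal_fraction x clonal VAF estimate,
    else "clonal" (boundary inclusive on the clonal side)."""
    if not (0 < clonal_vaf_estimate <= 1) or not (0 < subclonal_fraction <= 1):
        raise SchemaError("clonal_vaf_estimate and subclonal_fraction must be in (0, 1]")
    return "subclonal" if dna_vaf < subclonal_fraction * clonal_vaf_estimate else "clonal"


@dataclass
class RefMatchResult:
    matched: bool
    hits: list[tuple[str, int]] = field(default_factory=list)


def reference_match(
    peptide: str, proteome: Proteome, mode: str = "full", m: int = 8
) -> RefMatchResult:
    """Screen a candidate against the reference proteome.

    ``full`` mode requires the whole peptide as an exact substring of some
    record; ``kmer`` mode flags the peptide if any of its m-mers occurs.
    A match means the peptide is not tumor-specific (self peptide).
    Hit offsets are 1-based.
    """
    if not peptide:
        raise SchemaError("peptide must be non-empty")
    if mode == "full":
        hits = proteome.find(peptide)
        return RefMatchResult(matched=bool(hits), hits=hits)
    if mode == "kmer":
        if m > len(peptide):
            raise SchemaError(
                f"kmer size {m} exceeds peptide length {len(peptide)}"
            )
        hits: list[tuple[str, int]] = []
        seen_kmers: set[str] = set()
        for i in range(len(peptide) - m + 1):
            kmer = peptide[i : i + m]
            if kmer in seen_kmers:
                continue
            seen_kmers.add(kmer)
            hits.extend(proteome.find(kmer))
        return RefMatchResult(matched=bool(hits), hits=hits)
    raise SchemaError(f"unknown reference-match mode {mode!r}")


@dataclass(frozen=True)
class ProblematicSpec:
    """Residues problematic for peptide manufacturing.

    Tokens are either a residue letter ("C": flag cysteine anywhere) or
    residue@position ("M@1": methionine only at position 1).
    """

    tokens: tuple[str, ...] = ()

    @classmethod
    def parse(cls, text: str) -> "ProblematicSpec":
        tokens = tuple(tok.strip() for tok in text.split(",") if tok.strip())
        return cls(tokens=tokens)

    def rules(self) -> list[tuple[str, int | None]]:
        out: list[tuple[str, int | None]] = []
        for tok in self.tokens:
            m = re.fullmatch(r"([A-Z])(?:@(\d+))?", tok)
            if not m or m.group(1) not in AMINO_ACIDS:
                raise SpecError(f"malformed problematic-position token {tok!r}")
            out.append((m.group(1), int(m.group(2)) if m.group(2) else None))
        return out


def flag_problematic(peptide: str, spec: ProblematicSpec) -> list[int]:
    """Sorted 1-based positions of problematic residues in the peptide."""
    rules = spec.rules()
    flagged: set[int] = set()
    for pos, residue in enumerate(peptide, start=1):
        for letter, at in rules:
            if residue == letter and (at is None or at == pos):
                flagged.add(pos)
    return sorted(flagged)


@dataclass
class Candidate:
    """One (peptide, allele) scoring unit competing to be the best."""

    peptide_id: str
    allele: str
    mt_seq: str
    summary: BindingSummary
    anchor_verdict: str = "not_applicable"


_VERDICT_RANK = {"keep": 0, "not_applicable": 1, "deprioritize": 2}


def select_best_peptide(candidates: list[Candidate], thresholds: Thresholds) -> Candidate:
    """Deterministic winner among all (peptide, allele) candidates.

    Ranking: binding-filter pass first, then anchor verdict
    (keep > not_applicable > deprioritize), then ascending representative
    IC50, ascending median percentile, MT sequence, and finally
    (peptide id, allele) as an absolute tie-break.
    """
    if not candidates:
        raise SchemaError("select_best_peptide requires at least one candidate")

    def key(c: Candidate):
        pct = c.summary.median_percentile_mt
        return (
            0 if passes_binding_filter(c.summary, thresholds) else 1,
            _VERDICT_RANK[c.anchor_verdict],
            c.summary.representative_ic50(thresholds),
            pct if pct is not None else float("inf"),
            c.mt_seq,
            c.peptide_id,
            c.allele,
        )

    return min(candidates, key=key)


@dataclass
class VariantSummary:
    """Derived per-variant features feeding tier assignment."""

    variant_id: str
    best: Candidate
    allele_expr: float
    tsl: int | None
    clonality: str
    anchor_verdict: str
    failing_criteria: list[str] = field(default_factory=list)
    tier: str | None = None


def failing_criteria(summary: VariantSummary, thresholds: Thresholds) -> list[str]:
    failures: list[str] = []
    if not passes_binding_filter(summary.best.summary, thresholds):
        failures.append(FAIL_BINDING)
    if summary.allele_expr == 0:
        failures.append(FAIL_NOEXPR)
    elif summary.allele_expr < thresholds.allele_expr_low:
        failures.append(FAIL_LOWEXPR)
    if summary.tsl is not None and summary.tsl > thresholds.tsl_max:
        failures.append(FAIL_TSL)
    if summary.clonality == "subclonal":
        failures.append(FAIL_SUBCLONAL)
    if summary.anchor_verdict == "deprioritize":
        failures.append(FAIL_ANCHOR)
    return failures


def tier_from_failures(failures) -> str:
    """Pure ladder function of the failing-criteria set."""
    fs = set(failures)
    if not fs:
        return "Pass"
    if FAIL_BINDING in fs or len(fs) >= 2:
        return "Poor"
    (only,) = fs
    return _SINGLE_FAILURE_TIERS.get(only, "Poor")


def assign_tier(summary: VariantSummary, thresholds: Thresholds) -> str:
    """Populate ``failing_criteria`` and ``tier`` on the summary."""
    summary.failing_criteria = failing_criteria(summary, thresholds)
    summary.tier = tier_from_failures(summary.failing_criteria)
    return summary.tier


def tier_rank(tier: str) -> int:
    return TIER_LADDER.index(tier)


def count_passing(
    peptide_summaries: dict[str, dict[str, BindingSummary]],
    transcript_peptides: dict[str, tuple[str, ...]],
    thresholds: Thresholds,
) -> tuple[int, int]:
    """(passing peptides, passing transcripts) for one variant.

    A peptide passes if it clears the binding filter on at least one
    allele; a transcript passes if it yields at least one passing peptide.
    """
    passing_peptides = {
        pid
        for pid, per_allele in peptide_summaries.items()
        if any(passes_binding_filter(s, thresholds) for s in per_allele.values())
    }
    passing_transcripts = sum(
        1
        for pids in transcript_peptides.values()
        if any(pid in passing_peptides for pid in pids)
    )
    return len(passing_peptides), passing_transcripts


def flag_genes_of_interest(
    rows: list[AggregateReportRow], gene_set: set[str]
) -> list[AggregateReportRow]:
    """Set ``gene_of_interest`` by exact, case-sensitive gene-name match."""
    for row in rows:
        row.gene_of_interest = row.gene in gene_set
    return rows


SUPPLEMENTAL_IC50_COLUMN = "IC50 MT (Class II)"
SUPPLEMENTAL_PERCENTILE_COLUMN = "%ile MT (Class II)"


def attach_supplemental(
    rows: list[AggregateReportRow], supplemental: dict[str, SupplementalRecord]
) -> list[AggregateReportRow]:
    """Left-join median class II summaries onto the report rows.

    Rows without supplemental data keep NA; supplemental-only variants are
    ignored with a warning.  Tiers are never changed — rescuing a poor
    class I binder on good class II data is the reviewer's call.
    """
    known = {row.variant_id for row in rows}
    orphans = sorted(set(supplemental) - known)
    if orphans:
        warnings.warn(
            f"supplemental rows for unknown variant(s) ignored: {', '.join(orphans)}",
            stacklevel=2,
        )
    for row in rows:
        rec = supplemental.get(row.variant_id)
        if rec is None:
            row.extra.setdefault(SUPPLEMENTAL_IC50_COLUMN, "NA")
            row.extra.setdefault(SUPPLEMENTAL_PERCENTILE_COLUMN, "NA")
        else:
            row.extra[SUPPLEMENTAL_IC50_COLUMN] = fmt_number(rec.median_ic50, 3)
            row.extra[SUPPLEMENTAL_PERCENTILE_COLUMN] = fmt_number(rec.median_percentile, 2)
    return rows
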