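"""Prediction-algorithm registry, score aggregation, prediction counting and
the patient harmonic-mean best rank (PHBR).

The registry mirrors the ensemble a modern class I pipeline runs: 8 binding
predictors, 3 elution (mass-spectrometry presentation) predictors and 2
immunogenicity predictors — 13 algorithms in total for class I — plus 4
class II binding predictors.  Scores themselves always come from inputs or
the mock scorers in :mod:`neoprio.fixtures`; the real tools are never
invoked here.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .config import Thresholds
from .errors import SchemaError
from .io_formats import BindingScore

CLASS_I_BINDING = (
    "MHCflurry",
    "MHCnuggetsI",
    "NetMHC",
    "NetMHCcons",
    "NetMHCpan",
    "PickPocket",
    "SMM",
    "SMMPMBEC",
)
CLASS_I_ELUTION = ("BigMHC_EL", "MHCflurryEL", "NetMHCpanEL")
CLASS_I_IMMUNOGENICITY = ("BigMHC_IM", "DeepImmuno")
CLASS_II_BINDING = ("MHCnuggetsII", "NNalign", "NetMHCIIpan", "SMMalign")
CLASS_II_ELUTION = ("NetMHCIIpanEL",)

_REGISTRY = {
    ("I", "binding"): CLASS_I_BINDING,
    ("I", "elution"): CLASS_I_ELUTION,
    ("I", "immunogenicity"): CLASS_I_IMMUNOGENICITY,
    ("II", "binding"): CLASS_II_BINDING,
    ("II", "elution"): CLASS_II_ELUTION,
    ("II", "immunogenicity"): (),
}


def registry_contents(mhc_class: str, kind: str = "all") -> tuple[str, ...]:
    """Algorithm names for an MHC class and kind ("binding", "elution",
    "immunogenicity" or "all")."""
    if mhc_class not in ("I", "II"):
        raise SchemaError(f"unknown MHC class {mhc_class!r}")
    if kind == "all":
        return (
            _REGISTRY[(mhc_class, "binding")]
            + _REGISTRY[(mhc_class, "elution")]
            + _REGISTRY[(mhc_class, "immunogenicity")]
        )
    if (mhc_class, kind) not in _REGISTRY:
        raise SchemaError(f"unknown algorithm kind {kind!r}")
    return _REGISTRY[(mhc_class, kind)]


@dataclass
class PredictionRecord:
    """One algorithm's score for one peptide on one allele."""

    peptide_id: str
    allele: str
    algorithm: str
    kind: str = "binding"
    ic50: float | None = None
    percentile: float | None = None
    elution_score: float | None = None
    immunogenicity_score: float | None = None

    def __post_init__(self) -> None:
        if self.ic50 is not None and self.ic50 <= 0:
            raise SchemaError(f"IC50 must be positive, got {self.ic50}")
        if self.percentile is not None and not (0 <= self.percentile <= 100):
            raise SchemaError(f"percentile out of [0, 100]: {self.percentile}")
        for name in ("elution_score", "immunogenicity_score"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise SchemaError(f"{name} out of [0, 1]: {v}")


@dataclass
class BindingSummary:
    """Aggregated binding metrics for one peptide on one allele."""

    peptide_id: str
    allele: str
    median_ic50_mt: float
    lowest_ic50_mt: float
    median_percentile_mt: float | None = None
    median_ic50_wt: float | None = None

    def representative_ic50(self, thresholds: Thresholds) -> float:
        return (
            self.lowest_ic50_mt
            if thresholds.aggregate_metric == "lowest"
            else self.median_ic50_mt
        )


def aggregate_scores(records, wt_records=None) -> BindingSummary:
    """Median/lowest IC50 and median percentile across binding algorithms.

    ``records`` are one peptide+allele's MT binding records; an even count
    medians to the mean of the two central values.  Algorithms without a
    percentile simply do not contribute to the percentile median.  WT
    records, when given, contribute a WT median IC50.
    """
    binding = [r for r in records if r.kind == "binding" and r.ic50 is not None]
    if not binding:
        raise SchemaError("no binding predictions to aggregate")
    peptide_ids = {r.peptide_id for r in binding}
    alleles = {r.allele for r in binding}
    if len(peptide_ids) > 1 or len(alleles) > 1:
        raise SchemaError("aggregate_scores expects records for a single peptide and allele")
    ic50s = [r.ic50 for r in binding]
    percentiles = [r.percentile for r in binding if r.percentile is not None]
    wt_median = None
    if wt_records:
        wt_ic50s = [r.ic50 for r in wt_records if r.kind == "binding" and r.ic50 is not None]
        if wt_ic50s:
            wt_median = statistics.median(wt_ic50s)
    return BindingSummary(
        peptide_id=binding[0].peptide_id,
        allele=binding[0].allele,
        median_ic50_mt=statistics.median(ic50s),
        lowest_ic50_mt=min(ic50s),
        median_percentile_mt=statistics.median(percentiles) if percentiles else None,
        median_ic50_wt=wt_median,
    )


def summarize_binding(
    peptide_id: str,
    allele: str,
    mt_scores: dict[str, BindingScore],
    wt_scores: dict[str, BindingScore] | None = None,
) -> BindingSummary:
    """Aggregate from a metrics-bundle score block (algorithm -> score)."""
    records = [
        PredictionRecord(
            peptide_id=peptide_id,
            allele=allele,
            algorithm=alg,
            ic50=s.ic50,
            percentile=s.percentile,
        )
        for alg, s in mt_scores.items()
    ]
    wt_records = None
    if wt_scores:
        wt_records = [
            PredictionRecord(
                peptide_id=peptide_id,
                allele=allele,
                algorithm=alg,
                ic50=s.ic50,
                percentile=s.percentile,
            )
            for alg, s in wt_scores.items()
        ]
    return aggregate_scores(records, wt_records)


def count_predictions(n_peptides: int, n_alleles: int, n_algorithms: int) -> int:
    """Total peptide-MHC predictions: peptides x alleles x algorithms.

    With the 38 peptides of an interior SNV, 6 class I alleles and all 13
    class I algorithms this is 2964.
    """
    for n in (n_peptides, n_alleles, n_algorithms):
        if n < 0 or int(n) != n:
            raise SchemaError("counts must be non-negative integers")
    return n_peptides * n_alleles * n_algorithms


def compute_phbr(best_rank_per_allele) -> float:
    """Harmonic mean of the best prediction rank per patient allele."""
    ranks = list(best_rank_per_allele)
    if not ranks:
        raise SchemaError("PHBR requires at least one allele rank")
    if any(r <= 0 for r in ranks):
        raise SchemaError("PHBR ranks must be positive")
    return len(ranks) / sum(1.0 / r for r in ranks)


def passes_binding_filter(summary: BindingSummary, thresholds: Thresholds) -> bool:
    """Inclusive binding filter: representative IC50 <= 500 nM by default,
    optionally also median percentile <= 2."""
    ok = summary.representative_ic50(thresholds) <= thresholds.binding_threshold_nm
    if ok and thresholds.use_percentile:
        ok = (
            summary.median_percentile_mt is not None
            and summary.median_percentile_mt <= thresholds.percentile_threshold
        )
    return ok
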