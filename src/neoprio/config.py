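"""Pipeline configuration: binding/tiering thresholds and their defaults.

The defaults follow the published prioritization guidance: candidates with a
predicted binding affinity of 500 nM or less and a percentile rank of 2 or
less are considered good binders, transcripts of support level 1 are
preferred, and a variant whose DNA VAF falls below half the clonal VAF
estimate is treated as subclonal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .errors import SpecError

#: Tier vocabulary, best to worst.  "Pass" means no criterion failed; the
#: middle tiers name the single criterion that failed; "Poor" collects
#: binding failures and multi-criterion failures.
TIER_LADDER: tuple[str, ...] = ("Pass", "Anchor", "Subclonal", "LowExpr", "NoExpr", "Poor")

#: Evaluation states a reviewer can assign to a variant.
EVALUATIONS: tuple[str, ...] = ("Accept", "Reject", "Review", "Pending")


@dataclass
class Thresholds:
    """All tunable cutoffs used by score aggregation and tier assignment.

    Attributes
    ----------
    binding_threshold_nm:
        Maximum aggregated MT IC50 (nM) for a peptide to count as a good
        binder.  Inclusive: exactly 500 nM passes.
    percentile_threshold:
        Maximum aggregated MT percentile rank; applied conjunctively only
        when ``use_percentile`` is true.  Inclusive.
    use_percentile:
        Whether the percentile criterion participates in the binding filter.
    aggregate_metric:
        Which aggregate ("median" or "lowest") of the per-algorithm IC50s
        represents a peptide in filtering and reporting.
    allele_expr_low:
        Allele expression (gene TPM x RNA VAF) below which an expressed
        variant is flagged LowExpr.
    subclonal_fraction:
        A variant is subclonal when DNA VAF < this fraction of the clonal
        VAF estimate.
    tsl_max:
        Highest acceptable transcript support level (1 = best).
    mass_threshold:
        Cumulative anchor-probability mass that defines the anchor-position
        set of an allele/length profile.
    ref_match_mode:
        "full" (exact substring) or "kmer" (any m-mer substring) reference
        proteome matching.
    kmer_size:
        m for kmer-mode reference matching.
    """

    binding_threshold_nm: float = 500.0
    percentile_threshold: float = 2.0
    use_percentile: bool = False
    aggregate_metric: str = "median"
    allele_expr_low: float = 1.0
    subclonal_fraction: float = 0.5
    tsl_max: int = 1
    mass_threshold: float = 0.8
    ref_match_mode: str = "full"
    kmer_size: int = 8

    def __post_init__(self) -> None:
        if self.aggregate_metric not in ("median", "lowest"):
            raise SpecError(f"aggregate_metric must be 'median' or 'lowest', got {self.aggregate_metric!r}")
        if self.ref_match_mode not in ("full", "kmer"):
            raise SpecError(f"ref_match_mode must be 'full' or 'kmer', got {self.ref_match_mode!r}")
        if not (0 < self.subclonal_fraction <= 1):
            raise SpecError("subclonal_fraction must be in (0, 1]")
        if not (0 < self.mass_threshold <= 1):
            raise SpecError("mass_threshold must be in (0, 1]")
        for name in ("binding_threshold_nm", "percentile_threshold", "allele_expr_low", "tsl_max", "kmer_size"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")

    def replace(self, **kwargs) -> "Thresholds":
        return dataclasses.replace(self, **kwargs)


def load_thresholds(path: str) -> Thresholds:
    """Load thresholds from a YAML mapping; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SpecError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(Thresholds)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise SpecError(f"unknown config keys: {', '.join(unknown)}")
    return Thresholds(**data)
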