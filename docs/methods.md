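# Methods

## Problem and model

Somatic mutations in a tumor create peptides absent from the normal
proteome. When such a peptide is presented by one of the patient's MHC
class I molecules it can be recognized by T cells, which makes it a
candidate for a personalized vaccine. Selecting candidates requires
integrating several layers of evidence per variant: which transcripts carry
it and how confidently they are annotated (TSL, biotype), how strongly the
mutant peptide is predicted to bind each HLA allele across an ensemble of
algorithms, whether the mutation sits on an MHC-anchor position, whether
the variant is expressed and clonal, and whether the peptide accidentally
occurs in the normal proteome. This package implements that evidence
integration as a deterministic pipeline producing a per-variant aggregate
report with a prioritization tier.

### Peptide enumeration

A variant is applied to each transcript's protein sequence. Missense
variants substitute one residue; in-frame indels splice the alternate
residues in place of the reference run; frameshifts replace the suffix from
the first altered residue with a novel tail, truncated at the first stop
codon. Candidate peptides are all windows of the configured lengths
(default 8–11, the class I range) that lie fully inside the mutant protein
and cover at least one mutated residue. For an interior single substitution
this yields one window per register per length, i.e. 8+9+10+11 = 38
distinct peptides; with 6 class I alleles and the 13-algorithm class I
ensemble that is 38 × 6 × 13 = 2964 predictions, which is why the
downstream aggregation exists at all. Wild-type partner peptides are cut
from the same coordinates of the unmutated protein for equal-length
substitutions only; for length-changing variants (in-frame indels,
frameshifts) the same-coordinate wild-type window is not comparable
position-by-position, so those pairs carry no WT sequence and all
WT-dependent logic reports "not applicable" rather than 0. Duplicate mutant
sequences within a transcript are removed; transcripts yielding identical
candidate lists are grouped into transcript sets (TS1, TS2, … keyed by the
lexicographically smallest member, so grouping is order-invariant).

### Score aggregation

Per peptide and allele, the per-algorithm IC50s are summarized by their
median (even counts average the two central values) and minimum, and the
percentile ranks by their median over the algorithms that provide one. No
imputation: absent algorithms simply do not contribute. The binding filter
is inclusive — median (or, configurably, lowest) IC50 ≤ 500 nM, and when
enabled percentile ≤ 2. The patient harmonic-mean best rank
(PHBR = n / Σ 1/rᵢ over the best rank per allele) is provided for
multi-allele presentation summaries.

### Anchor scenarios

Each allele/length combination has a normalized per-position anchor
probability vector. The anchor set is the smallest set of
highest-probability positions whose cumulative mass reaches the
`mass_threshold` (default 0.8; the literature this reconstructs does not
print a value, so the parameter is configurable and documented as a
reconstruction). A candidate is deprioritized only when *all* its mutated
positions are anchors (the conservative choice: a multi-residue variant
with any TCR-exposed change remains visible) *and* the wild-type peptide is
itself a strong binder (median IC50 ≤ binding threshold) — that combination
risks central tolerance. The heatmap view selects at most 15 MT/WT pairs
per allele, by ascending median MT IC50 with lexicographic tie-break.

### Tiering

Failing criteria per variant, evaluated on its best peptide: binding
(aggregated IC50 above threshold), expression (allele expression
= gene TPM × RNA VAF; 0 → NoExpr, below `allele_expr_low` → LowExpr),
transcript support (TSL > `tsl_max`), clonality (DNA VAF below
`subclonal_fraction` × clonal VAF estimate, the estimate defaulting to
min(0.5, max cohort DNA VAF); the boundary is inclusive on the clonal
side), and anchor (verdict deprioritize). The ladder is Pass > Anchor >
Subclonal > LowExpr > NoExpr > Poor: a named middle tier applies when
exactly that criterion fails; a binding failure or ≥ 2 failures give Poor.
The ladder names are a reconstruction — the criteria are published, the
vocabulary is not — and a lone TSL failure also maps to Poor since the
ladder names no TSL tier. Best-peptide selection is a total order
(filter pass, anchor verdict, IC50, percentile, sequence, then ids), so the
report is deterministic under any input permutation. Tiering is monotone:
improving IC50 or allele expression never worsens a tier.

## Tunable parameters

| Parameter | Default | Units / meaning |
|---|---|---|
| `binding_threshold_nm` | 500 | nM; inclusive good-binder cutoff |
| `percentile_threshold` | 2 | percentile rank; inclusive, off by default |
| `use_percentile` | false | add the percentile criterion conjunctively |
| `aggregate_metric` | median | median or lowest IC50 represents a peptide |
| `allele_expr_low` | 1.0 | TPM × VAF below which LowExpr fires (no published value exists; 1.0 marks roughly one transcript-per-cell equivalents attributable to the mutant allele) |
| `subclonal_fraction` | 0.5 | fraction of the clonal VAF estimate |
| `tsl_max` | 1 | highest acceptable transcript support level |
| `mass_threshold` | 0.8 | cumulative anchor-probability mass |
| `ref_match_mode`, `kmer_size` | full, 8 | proteome screen: whole-peptide or any-8-mer |

## Synthetic cohorts

The generator emulates what an upstream variant-calling plus
epitope-prediction pipeline hands to the prioritization step. Per variant
it draws a random protein (45–60 residues — long enough for every register
of an 11-mer around an interior mutation, short enough to keep test
cohorts fast), an interior mutation position, 1–2 transcripts (a second
isoform repeats the first or differs, exercising transcript-set grouping),
clonal DNA VAFs in 0.40–0.50 against subclonal ones in 0.05–0.19 (clonal
VAF estimate ≈ 0.5, cutoff ≈ 0.25), expression 10–100 TPM with RNA VAF
0.2–0.8, and a 12–18-residue frameshift tail for a configurable fraction of
variants. Mock scores are seeded hash functions of (peptide, allele,
algorithm): log-uniform IC50s with a monotone percentile map, uniform
elution/immunogenicity scores. They are deliberately non-biological — no
sequence feature influences them.

Each variant is planted with at most one failure mode (none, no
expression, subclonal, anchor, or poor binding), recorded in a manifest.
Planting works by range control: the designated best 9-mer gets strong
scores (20–300 nM) on one allele while every other peptide–allele
combination is weak (1500–50000 nM); anchor-category variants place the
mutation on peptide position 2 (an anchor under the two-anchor fixture
profiles, positions 2 and C-terminus at 0.45 each) and make the wild-type
partner a strong binder, other categories place it on exposed position 5.
All transcripts carry TSL 1 so a planted variant fails exactly its planted
criterion; TSL tiering is exercised by unit tests instead. Wild-type
proteins all enter the synthetic proteome, so WT peptides reference-match
by construction.

What passing planted-truth tests shows — and does not. Recovery of planted
tiers demonstrates that the plumbing from scores to tiers is correct under
separable, single-failure conditions. Real tumors violate those
conditions: failures co-occur, binding scores correlate with sequence,
anchor profiles vary by allele beyond two positions, expression and
clonality are noisy estimates. The tests validate the engine, not the
biology.

## Numerical choices

TSV numbers are fixed-precision (IC50 3 decimals, percentiles/VAFs 2,
expression 3, allele expression 6 so the product identity holds within
1e-6); anchor probabilities are serialized losslessly via `repr`. Median of
an even count is the mean of the central pair. The anchor-set accumulation
uses a 1e-12 slack on the mass comparison so thresholds like 0.9 are not
missed to floating-point rounding, and ties break toward smaller positions,
making the set deterministic and monotone in the threshold. Report ordering
is (tier rank, representative IC50, variant id). Comments are
backslash-escaped because TSV has no quoting convention.

## Problem sizes

The default test cohorts are 12 variants (unit/pipeline tests) and 100
variants (planted-truth recovery); oracle suites run 100–500 random
instances per property. These sizes give full coverage of every planted
category while keeping the whole suite fast.

## Known limitations

- Variants enter with per-transcript protein context; the package does not
  translate cDNA, resolve splice graphs, or call variants from VCF/BAM.
- Real binding/elution/immunogenicity predictors are represented by a name
  registry plus mock scorers; no model is trained or invoked.
- Anchor probabilities are fixture inputs, not derived from structural or
  binding-matrix data.
- Class II support is limited to the supplemental-summary join; phased
  proximal variants, fusions and splice-derived antigens are out of scope.
- The NeoFox default-visible column list is name-based and version-dependent
  by design; import is schema-light.
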