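# neoprio

Neoantigen candidate prioritization: mutant-peptide enumeration,
multi-algorithm MHC score aggregation, anchor-scenario classification and
tier assignment, as a tested Python library with a thin CLI.

## The problem

Tumor-specific mutations create peptides (neoantigens) that MHC class I
molecules can present to T cells, the basis of personalized cancer
vaccines. Even a single interior SNV, sampled at every register of the
class I lengths 8–11, yields 8+9+10+11 = 38 distinct mutant peptides; with
6 patient HLA alleles and a 13-algorithm prediction ensemble that is
38 × 6 × 13 = 2964 peptide–MHC predictions to reconcile — per variant.
This package implements the evidence integration that turns that volume
into a reviewable per-variant report:

- **Enumeration** — apply missense / in-frame indel / frameshift variants
  to each transcript's protein, cut every length-8..11 window covering a
  mutated residue, pair mutant (MT) with wild-type (WT) peptides, and group
  transcripts yielding identical candidate lists into transcript sets.
- **Aggregation** — median and lowest IC50 (nM) and median percentile rank
  across the algorithm ensemble (8 class I binding, 3 elution,
  2 immunogenicity; 4 class II binding), plus the patient harmonic-mean
  best rank PHBR = n / Σ 1/rᵢ.
- **Screening** — allele/length-specific anchor-position sets (smallest
  high-probability position set covering 0.8 cumulative mass); a candidate
  whose mutation hides entirely on anchors while its WT is a strong binder
  is deprioritized as a tolerance risk. Reference-proteome substring
  matching and problematic-residue flagging (e.g. `C`, `M@1`) screen the
  best peptide.
- **Tiering** — per-variant failing criteria over binding
  (median IC50 ≤ 500 nM, percentile ≤ 2, both inclusive), allele expression
  (RNA Expr × RNA VAF), transcript support level, clonality
  (DNA VAF < ½ × clonal VAF) and anchor scenario, collapsed to the ladder
  Pass > Anchor > Subclonal > LowExpr > NoExpr > Poor.
- **Review session** — accept/reject/review evaluations with comments,
  tallies, and lossless TSV export/reload (XLSX export is one-way).
- **Interop** — NeoFox-style and arbitrary custom candidate TSVs with
  group-by / sort-by / feature-selection views and axis transforms.

Real predictors are represented by a name registry and seeded mock
scorers; the package never invokes binding models. See `docs/methods.md`
for the model and `docs/formats.md` for the file dialects.

## Worked example

```python
import neoprio as np

cohort = np.simulate_cohort(np.SimulationConfig(seed=7, n_variants=8))
rows, session = np.run_pipeline(cohort.bundle, cohort.proteome, cohort.anchors)
for r in rows:
    print(f"{r.variant_id:22s} {r.gene:7s} {r.aa_change:7s} {r.tier:10s} "
          f"{r.best_peptide:12s} {r.allele:12s} {r.ic50_mt:8.1f} {r.allele_expr:8.3f}")
print(session.tally())
```

prints

```
chr8-5705105-A-G       GENE8   S27F    Pass       FASCFKEHS    HLA-B*08:01      32.8   20.393
chr2-17617150-T-C      GENE2   G16W    Pass       PIFDWFIIA    HLA-B*07:02      52.2    5.164
chr1-25540967-A-G      GENE1   V24R    Pass       FLQFREWLV    HLA-A*02:01     117.9    9.163
chr6-21937455-G-T      GENE6   S20R    Anchor     QRVPTLHIM    HLA-A*02:01      94.7   16.633
chr7-24929941-C-A      GENE7   S26P    Subclonal  FYPMPFLYF    HLA-B*08:01      41.0   35.909
chr3-41418272-G-C      GENE3   S40T    Subclonal  PIHTTNAAK    HLA-C*07:02      51.9   63.373
chr5-35601669-T-C      GENE5   T31F    NoExpr     KPFVFWSMD    HLA-A*02:01      72.2    0.000
chr4-9046596-T-G       GENE4   V22F    Poor       YTYFHKRTVS   HLA-B*07:02    2170.6   36.128
{'Accept': 0, 'Reject': 0, 'Review': 0}
```

Rows are ordered by tier, then aggregated mutant IC50 (nM, lower = stronger
binding), then variant id. `GENE6` is a strong binder whose mutation sits
on an anchor position with a well-presented wild-type peptide (tolerance
risk → Anchor); `GENE5` has no mutant-allele expression; `GENE4`'s best
peptide binds too weakly (2170 nM > 500 nM → Poor). The same flow is
available from the shell:

```bash
neoprio simulate --seed 7 --n-variants 8 --out-dir fixtures/
neoprio run --metrics fixtures/metrics.json --proteome fixtures/proteome.fasta \
            --anchors fixtures/anchors.tsv --out aggregate.tsv
neoprio session --aggregate aggregate.tsv --set chr8-5705105-A-G=Accept
```

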