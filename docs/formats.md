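# File formats

All formats are defined by this package. They cover the content classes a
variant-to-neoantigen pipeline produces (variant summaries, per-algorithm
scores, reference sequences); they do not aim for byte compatibility with
any specific upstream tool's release, whose schemas are versioned
independently.

## Aggregate report (TSV)

One row per variant, tab-separated, LF line endings, `NA` for missing
values. Column order is fixed; unknown columns read from disk are preserved
and appended after the known ones on write, making `write(read(f)) == f`
for canonical files.

| Column | Content |
|---|---|
| ID | `chrom-pos-ref-alt`, 1-based genomic position; unique per file |
| Gene | gene symbol |
| AA Change | protein-level change, e.g. `R175H`, `K10fs` |
| Pos | comma-joined 1-based mutated positions within the best peptide |
| Best Peptide | best mutant peptide sequence |
| Best Transcript | transcript coding for the best peptide |
| TSL | transcript support level (1 = best) or `NA` |
| Allele | HLA allele of the best prediction |
| IC50 MT / IC50 WT | aggregated binding affinity in nM (3 decimals); WT only reported when the MT passes the binding filter |
| %ile MT | aggregated percentile rank (2 decimals) |
| Num Passing Peptides / Transcripts | counts meeting the binding filter |
| RNA Expr | gene expression, TPM (3 decimals) |
| RNA VAF / DNA VAF | variant allele fractions (2 decimals) |
| Allele Expr | RNA Expr × RNA VAF (6 decimals, so the identity survives the round-trip) |
| RNA Depth | RNA read depth |
| Tier | one of `Pass, Anchor, Subclonal, LowExpr, NoExpr, Poor` |
| Ref Match | `True`/`False`: best peptide found in the reference proteome |
| Prob Pos | comma-joined problematic positions, or `None` |
| Evaluation | `Accept`, `Reject`, `Review` or `Pending` (default) |
| Comment | free text; `\t`, `\n`, `\r`, `\\` backslash-escaped |
| Gene of Interest | `True`/`False` |

Example (columns elided):

```
ID	Gene	AA Change	Pos	Best Peptide	...	Tier	Evaluation	Comment
chr5-1295228-G-A	TERT	R131H	5	KLMNPQRST	...	Pass	Pending
```

XLSX export writes the same table to a single sheet and is one-way:
sessions reload only from TSV.

## Metrics bundle (JSON)

A reconstruction of the per-variant detail file such pipelines emit; the
exact upstream schema is not published, so this dialect is defined here and
validated on read. Top level:

```json
{
  "format": "neoprio-metrics-v1",
  "hla_alleles": ["HLA-A*02:01", "..."],
  "variants": {
    "chr1-123-A-T": {
      "gene": "GENE1", "variant_class": "missense",
      "protein_pos": 17, "ref_aa": "D", "alt_aa": "Y", "aa_change": "D17Y",
      "dna_vaf": 0.45, "rna_vaf": 0.4, "rna_depth": 120, "gene_expr": 35.1,
      "novel_tail": null,
      "transcripts": [
        {"transcript_id": "T0001.1", "tsl": 1, "biotype": "protein_coding",
         "expression": 12.3, "transcript_set_id": "TS1",
         "peptide_ids": ["p0.1", "p0.2"], "protein_seq": "MAC..."}
      ],
      "peptides": {
        "p0.1": {
          "mt_seq": "KLMNYQRST", "wt_seq": "KLMNDQRST",
          "mutated_positions": [5],
          "mt_binding": {"HLA-A*02:01": {"NetMHCpan": {"ic50": 55.2, "percentile": 0.4}}},
          "wt_binding": {"HLA-A*02:01": {"NetMHCpan": {"ic50": 4021.0, "percentile": 42.1}}},
          "elution": {"HLA-A*02:01": {"MHCflurryEL": 0.91}},
          "immunogenicity": {"HLA-A*02:01": {"DeepImmuno": 0.44}}
        }
      }
    }
  }
}
```

Validation enforces: every `peptide_ids` entry resolves, every peptide is
referenced by at least one transcript, and all score alleles are in
`hla_alleles`. `protein_seq` lets the pipeline re-enumerate peptides;
`novel_tail` carries the frameshift's novel residue run (a `*` terminates
it).

## Reference proteome (FASTA)

Standard FASTA; residues restricted to the 20 canonical amino acids plus
`X`; lowercase is uppercased on read. Line wrapping is irrelevant.

## Gene list (TSV)

One gene name per line; deduplicated and trimmed; matching against the
report is exact and case-sensitive.

## Supplemental class II summary (TSV)

Columns `ID`, `Median IC50`, `Median Percentile`, keyed by variant id.
Joined onto the aggregate report as extra columns `IC50 MT (Class II)` and
`%ile MT (Class II)`; never changes tiers.

## Anchor profiles (TSV)

Columns `allele`, `length`, then `p1..pL` per-position probabilities
(sum 1 per row); one row per allele/length combination.

```
allele	length	p1	p2	...	p9
HLA-A*02:01	9	0.0142	0.45	...	0.45
```
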