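"""On-disk artifacts: aggregate report TSV, metrics JSON, proteome FASTA,
gene lists and supplemental class II tables.

The TSV and JSON dialects are defined by this package and documented with
examples in docs/formats.md.  The aggregate TSV is written byte-stably:
fixed column order, tab separator, LF line endings, ``NA`` for missing
values, IC50s with up to 3 decimals, percentiles and fractions with up to 2
(allele expression keeps 6 so that the Allele Expr = RNA Expr x RNA VAF
identity survives a round-trip).  Free-text comments are backslash-escaped
(``\\t``, ``\\n``, ``\\r``, ``\\\\``) because TSV has no standard quoting.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import EVALUATIONS, TIER_LADDER
from .errors import IntegrityError, SchemaError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: X (unknown residue) is tolerated in proteome records.
PROTEOME_ALPHABET = AMINO_ACIDS | {"X"}


# ---------------------------------------------------------------------------
# number / text formatting helpers
# ---------------------------------------------------------------------------

def fmt_number(value: float | int | None, decimals: int) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "True" if value else "False"
    text = f"{value:.{decimals}f}"
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return text


def _parse_float(cell: str, *, where: str) -> float | None:
    if cell == "NA" or cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise SchemaError(f"non-numeric value {cell!r} in {where}") from None


def _parse_int(cell: str, *, where: str) -> int | None:
    if cell == "NA" or cell == "":
        return None
    try:
        return int(cell)
    except ValueError:
        raise SchemaError(f"non-integer value {cell!r} in {where}") from None


def escape_text(text: str) -> str:
    """Backslash-escape characters that would break a TSV cell."""
    return (
        text.replace("\\", "\\\\")
        .replace("\t", "\\t")
        .replace("\n", "\\n")
        .replace("\r", "\\r")
    )


def unescape_text(text: str) -> str:
    out: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            mapped = {"\\": "\\", "t": "\t", "n": "\n", "r": "\r"}.get(nxt)
            if mapped is not None:
                out.append(mapped)
                i += 2
                continue
        out.append(ch)
        i += 1
    return "".join(out)


def _positions_to_str(positions: tuple[int, ...]) -> str:
    return ", ".join(str(p) for p in positions) if positions else "None"


def _positions_from_str(cell: str, *, where: str) -> tuple[int, ...]:
    if cell in ("None", "NA", ""):
        return ()
    try:
        return tuple(int(tok.strip()) for tok in cell.split(","))
    except ValueError:
        raise SchemaError(f"malformed position list {cell!r} in {where}") from None


# ---------------------------------------------------------------------------
# aggregate report rows
# ---------------------------------------------------------------------------

@dataclass
class AggregateReportRow:
    """One variant-level line of the aggregate report.

    ``variant_id`` is ``chrom-pos-ref-alt`` with a 1-based genomic position.
    ``pos_in_core`` holds the 1-based mutated residue positions within
    ``best_peptide``; ``prob_pos`` the problematic residue positions (empty
    tuple serialized as ``None``).  Unknown columns read from disk are kept
    verbatim in ``extra`` and appended after the known columns on write.
    """

    variant_id: str
    gene: str
    aa_change: str
    pos_in_core: tuple[int, ...]
    best_peptide: str
    best_transcript: str
    tsl: int | None
    allele: str
    ic50_mt: float | None
    percentile_mt: float | None
    ic50_wt: float | None
    num_passing_peptides: int
    num_passing_transcripts: int
    rna_expr: float | None
    rna_vaf: float | None
    allele_expr: float | None
    rna_depth: int | None
    dna_vaf: float | None
    tier: str
    ref_match: bool
    prob_pos: tuple[int, ...] = ()
    evaluation: str = "Pending"
    comment: str = ""
    gene_of_interest: bool = False
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos_in_core = tuple(self.pos_in_core)
        self.prob_pos = tuple(self.prob_pos)
        self.validate()

    def validate(self) -> None:
        if self.tier not in TIER_LADDER:
            raise SchemaError(f"unknown tier {self.tier!r} for {self.variant_id}")
        if self.evaluation not in EVALUATIONS:
            raise SchemaError(f"unknown evaluation {self.evaluation!r} for {self.variant_id}")
        if self.best_peptide and any(
            not (1 <= p <= len(self.best_peptide)) for p in self.pos_in_core
        ):
            raise SchemaError(f"pos_in_core outside best peptide for {self.variant_id}")
        if None not in (self.allele_expr, self.rna_expr, self.rna_vaf):
            if not math.isclose(
                self.allele_expr, self.rna_expr * self.rna_vaf, abs_tol=1e-6
            ):
                raise SchemaError(
                    f"allele_expr != rna_expr * rna_vaf for {self.variant_id}"
                )


def _bool_to_str(value: bool) -> str:
    return "True" if value else "False"


def _bool_from_str(cell: str, *, where: str) -> bool:
    if cell in ("True", "TRUE", "true"):
        return True
    if cell in ("False", "FALSE", "false"):
        return False
    raise SchemaError(f"non-boolean value {cell!r} in {where}")


# (header, serializer, parser) per known column, in on-disk order.
_COLUMNS: list[tuple[str, str]] = [
    ("ID", "variant_id"),
    ("Gene", "gene"),
    ("AA Change", "aa_change"),
    ("Pos", "pos_in_core"),
    ("Best Peptide", "best_peptide"),
    ("Best Transcript", "best_transcript"),
    ("TSL", "tsl"),
    ("Allele", "allele"),
    ("IC50 MT", "ic50_mt"),
    ("%ile MT", "percentile_mt"),
    ("IC50 WT", "ic50_wt"),
    ("Num Passing Peptides", "num_passing_peptides"),
    ("Num Passing Transcripts", "num_passing_transcripts"),
    ("RNA Expr", "rna_expr"),
    ("RNA VAF", "rna_vaf"),
    ("Allele Expr", "allele_expr"),
    ("RNA Depth", "rna_depth"),
    ("DNA VAF", "dna_vaf"),
    ("Tier", "tier"),
    ("Ref Match", "ref_match"),
    ("Prob Pos", "prob_pos"),
    ("Evaluation", "evaluation"),
    ("Comment", "comment"),
    ("Gene of Interest", "gene_of_interest"),
]
KNOWN_COLUMNS = [name for name, _ in _COLUMNS]
MANDATORY_COLUMNS = [name for name in KNOWN_COLUMNS if name not in ("Evaluation", "Comment")]


def _serialize_cell(row: AggregateReportRow, column: str) -> str:
    value = getattr(row, dict(_COLUMNS)[column])
    if column in ("ID", "Gene", "AA Change", "Best Peptide", "Best Transcript", "Allele", "Tier", "Evaluation"):
        return str(value)
    if column == "Comment":
        return escape_text(value)
    if column in ("Pos", "Prob Pos"):
        return _positions_to_str(value)
    if column in ("Ref Match", "Gene of Interest"):
        return _bool_to_str(value)
    if column in ("TSL", "Num Passing Peptides", "Num Passing Transcripts", "RNA Depth"):
        return "NA" if value is None else str(value)
    if column in ("IC50 MT", "IC50 WT", "RNA Expr"):
        return fmt_number(value, 3)
    if column in ("%ile MT", "RNA VAF", "DNA VAF"):
        return fmt_number(value, 2)
    if column == "Allele Expr":
        return fmt_number(value, 6)
    raise AssertionError(column)


def write_aggregate_report(rows: list[AggregateReportRow], path, fmt: str = "tsv") -> None:
    """Write rows as TSV (round-trippable) or XLSX (one sheet, one-way)."""
    if not rows:
        raise SchemaError("cannot write an empty aggregate report")
    extra_columns: list[str] = []
    for row in rows:
        for name in row.extra:
            if name not in extra_columns:
                extra_columns.append(name)
    header = KNOWN_COLUMNS + extra_columns
    table = [header]
    for row in rows:
        cells = [_serialize_cell(row, col) for col in KNOWN_COLUMNS]
        cells += [escape_text(row.extra.get(col, "NA")) for col in extra_columns]
        table.append(cells)

    if fmt == "tsv":
        with open(path, "w", newline="") as fh:
            for cells in table:
                fh.write("\t".join(cells) + "\n")
    elif fmt == "xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "Aggregate Report"
        for cells in table:
            ws.append(cells)
        wb.save(path)
    else:
        raise SchemaError(f"unknown aggregate report format {fmt!r}")


def read_aggregate_report(path) -> list[AggregateReportRow]:
    """Read an aggregate report TSV written in the documented dialect."""
    with open(path, newline="") as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise SchemaError(f"{path}: empty file, expected a header row")
    header = lines[0].split("\t")
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise SchemaError(f"{path}: duplicate column {name!r}")
        seen.add(name)
    missing = [name for name in MANDATORY_COLUMNS if name not in seen]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    extra_columns = [name for name in header if name not in KNOWN_COLUMNS]
    index = {name: i for i, name in enumerate(header)}

    rows: list[AggregateReportRow] = []
    ids: dict[str, int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise SchemaError(f"{path}:{lineno}: expected {len(header)} cells, got {len(cells)}")

        def cell(name: str, default: str | None = None) -> str:
            if name not in index:
                return default  # type: ignore[return-value]
            return cells[index[name]]

        where = f"{path}:{lineno}"
        row = AggregateReportRow(
            variant_id=cell("ID"),
            gene=cell("Gene"),
            aa_change=cell("AA Change"),
            pos_in_core=_positions_from_str(cell("Pos"), where=where),
            best_peptide=cell("Best Peptide"),
            best_transcript=cell("Best Transcript"),
            tsl=_parse_int(cell("TSL"), where=where),
            allele=cell("Allele"),
            ic50_mt=_parse_float(cell("IC50 MT"), where=where),
            percentile_mt=_parse_float(cell("%ile MT"), where=where),
            ic50_wt=_parse_float(cell("IC50 WT"), where=where),
            num_passing_peptides=_parse_int(cell("Num Passing Peptides"), where=where),
            num_passing_transcripts=_parse_int(cell("Num Passing Transcripts"), where=where),
            rna_expr=_parse_float(cell("RNA Expr"), where=where),
            rna_vaf=_parse_float(cell("RNA VAF"), where=where),
            allele_expr=_parse_float(cell("Allele Expr"), where=where),
            rna_depth=_parse_int(cell("RNA Depth"), where=where),
            dna_vaf=_parse_float(cell("DNA VAF"), where=where),
            tier=cell("Tier"),
            ref_match=_bool_from_str(cell("Ref Match"), where=where),
            prob_pos=_positions_from_str(cell("Prob Pos"), where=where),
            evaluation=cell("Evaluation", "Pending") or "Pending",
            comment=unescape_text(cell("Comment", "") or ""),
            gene_of_interest=_bool_from_str(cell("Gene of Interest"), where=where),
            extra={name: unescape_text(cells[index[name]]) for name in extra_columns},
        )
        if row.variant_id in ids:
            raise SchemaError(
                f"{path}: duplicate variant id(s): {row.variant_id} "
                f"(lines {ids[row.variant_id]} and {lineno})"
            )
        ids[row.variant_id] = lineno
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# metrics bundle (JSON)
# ---------------------------------------------------------------------------

@dataclass
class BindingScore:
    ic50: float
    percentile: float | None = None

    def __post_init__(self) -> None:
        if self.ic50 is not None and self.ic50 <= 0:
            raise SchemaError(f"IC50 must be positive, got {self.ic50}")
        if self.percentile is not None and not (0 <= self.percentile <= 100):
            raise SchemaError(f"percentile must be in [0, 100], got {self.percentile}")


@dataclass
class PeptideEntry:
    peptide_id: str
    mt_seq: str
    wt_seq: str | None
    mutated_positions: tuple[int, ...]
    #: allele -> algorithm -> BindingScore, mutant peptide
    mt_binding: dict[str, dict[str, BindingScore]] = field(default_factory=dict)
    #: allele -> algorithm -> BindingScore, wild-type partner (absent for frameshift)
    wt_binding: dict[str, dict[str, BindingScore]] = field(default_factory=dict)
    #: allele -> algorithm -> score in [0, 1]
    elution: dict[str, dict[str, float]] = field(default_factory=dict)
    immunogenicity: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class TranscriptEntry:
    transcript_id: str
    tsl: int | None
    biotype: str
    expression: float
    peptide_ids: tuple[str, ...]
    transcript_set_id: str | None = None
    protein_seq: str | None = None


@dataclass
class VariantEntry:
    variant_id: str
    gene: str
    variant_class: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    aa_change: str
    dna_vaf: float
    rna_vaf: float
    rna_depth: int
    gene_expr: float
    transcripts: list[TranscriptEntry] = field(default_factory=list)
    peptides: dict[str, PeptideEntry] = field(default_factory=dict)
    novel_tail: str | None = None


@dataclass
class MetricsBundle:
    """Cross-linked per-variant transcript/peptide/score container."""

    hla_alleles: tuple[str, ...]
    variants: dict[str, VariantEntry] = field(default_factory=dict)

    def validate(self) -> None:
        alleles = set(self.hla_alleles)
        for vid, variant in self.variants.items():
            referenced: set[str] = set()
            for tx in variant.transcripts:
                dangling = [pid for pid in tx.peptide_ids if pid not in variant.peptides]
                if dangling:
                    raise IntegrityError(
                        f"variant {vid}, transcript {tx.transcript_id}: "
                        f"unknown peptide id(s): {', '.join(dangling)}"
                    )
                referenced.update(tx.peptide_ids)
            orphans = sorted(set(variant.peptides) - referenced)
            if orphans:
                raise IntegrityError(
                    f"variant {vid}: peptide(s) not referenced by any transcript: "
                    f"{', '.join(orphans)}"
                )
            for pid, pep in variant.peptides.items():
                for block in (pep.mt_binding, pep.wt_binding, pep.elution, pep.immunogenicity):
                    foreign = sorted(set(block) - alleles)
                    if foreign:
                        raise IntegrityError(
                            f"variant {vid}, peptide {pid}: scores for allele(s) "
                            f"outside the declared HLA set: {', '.join(foreign)}"
                        )


def _scores_to_json(block: dict[str, dict[str, BindingScore]]) -> dict:
    return {
        allele: {
            alg: {"ic50": s.ic50, "percentile": s.percentile}
            for alg, s in per_alg.items()
        }
        for allele, per_alg in block.items()
    }


def _scores_from_json(block: dict) -> dict[str, dict[str, BindingScore]]:
    return {
        allele: {
            alg: BindingScore(ic50=s["ic50"], percentile=s.get("percentile"))
            for alg, s in per_alg.items()
        }
        for allele, per_alg in block.items()
    }


def write_metrics(bundle: MetricsBundle, path) -> None:
    bundle.validate()
    doc = {
        "format": "neoprio-metrics-v1",
        "hla_alleles": list(bundle.hla_alleles),
        "variants": {
            vid: {
                "gene": v.gene,
                "variant_class": v.variant_class,
                "protein_pos": v.protein_pos,
                "ref_aa": v.ref_aa,
                "alt_aa": v.alt_aa,
                "aa_change": v.aa_change,
                "dna_vaf": v.dna_vaf,
                "rna_vaf": v.rna_vaf,
                "rna_depth": v.rna_depth,
                "gene_expr": v.gene_expr,
                "novel_tail": v.novel_tail,
                "transcripts": [
                    {
                        "transcript_id": tx.transcript_id,
                        "tsl": tx.tsl,
                        "biotype": tx.biotype,
                        "expression": tx.expression,
                        "transcript_set_id": tx.transcript_set_id,
                        "peptide_ids": list(tx.peptide_ids),
                        "protein_seq": tx.protein_seq,
                    }
                    for tx in v.transcripts
                ],
                "peptides": {
                    pid: {
                        "mt_seq": p.mt_seq,
                        "wt_seq": p.wt_seq,
                        "mutated_positions": list(p.mutated_positions),
                        "mt_binding": _scores_to_json(p.mt_binding),
                        "wt_binding": _scores_to_json(p.wt_binding),
                        "elution": p.elution,
                        "immunogenicity": p.immunogenicity,
                    }
                    for pid, p in v.peptides.items()
                },
            }
            for vid, v in bundle.variants.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


def read_metrics(path) -> MetricsBundle:
    """Read and validate a metrics JSON file; raises on dangling references."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(doc, dict) or "variants" not in doc or "hla_alleles" not in doc:
        raise SchemaError(f"{path}: not a metrics bundle (missing hla_alleles/variants)")
    bundle = MetricsBundle(hla_alleles=tuple(doc["hla_alleles"]))
    for vid, v in doc["variants"].items():
        entry = VariantEntry(
            variant_id=vid,
            gene=v["gene"],
            variant_class=v["variant_class"],
            protein_pos=v["protein_pos"],
            ref_aa=v["ref_aa"],
            alt_aa=v["alt_aa"],
            aa_change=v.get("aa_change", ""),
            dna_vaf=v["dna_vaf"],
            rna_vaf=v["rna_vaf"],
            rna_depth=v["rna_depth"],
            gene_expr=v["gene_expr"],
            novel_tail=v.get("novel_tail"),
        )
        for tx in v["transcripts"]:
            entry.transcripts.append(
                TranscriptEntry(
                    transcript_id=tx["transcript_id"],
                    tsl=tx["tsl"],
                    biotype=tx["biotype"],
                    expression=tx["expression"],
                    peptide_ids=tuple(tx["peptide_ids"]),
                    transcript_set_id=tx.get("transcript_set_id"),
                    protein_seq=tx.get("protein_seq"),
                )
            )
        for pid, p in v["peptides"].items():
            entry.peptides[pid] = PeptideEntry(
                peptide_id=pid,
                mt_seq=p["mt_seq"],
                wt_seq=p.get("wt_seq"),
                mutated_positions=tuple(p["mutated_positions"]),
                mt_binding=_scores_from_json(p.get("mt_binding", {})),
                wt_binding=_scores_from_json(p.get("wt_binding", {})),
                elution=p.get("elution", {}),
                immunogenicity=p.get("immunogenicity", {}),
            )
        bundle.variants[vid] = entry
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# reference proteome (FASTA)
# ---------------------------------------------------------------------------

class Proteome:
    """Named amino-acid sequences with substring search.

    Residues are restricted to the 20 canonical amino acids plus X; search
    offsets are 1-based.
    """

    def __init__(self, records: dict[str, str]):
        if not records:
            raise SchemaError("proteome must contain at least one record")
        for name, seq in records.items():
            seq = seq.upper()
            for offset, residue in enumerate(seq, start=1):
                if residue not in PROTEOME_ALPHABET:
                    raise SchemaError(
                        f"illegal residue {residue!r} in record {name!r} at offset {offset}"
                    )
            records[name] = seq
        self._records = dict(records)

    @property
    def records(self) -> dict[str, str]:
        return dict(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def names(self) -> list[str]:
        return list(self._records)

    def find(self, query: str) -> list[tuple[str, int]]:
        """All (record name, 1-based offset) occurrences of ``query``."""
        hits: list[tuple[str, int]] = []
        for name, seq in self._records.items():
            start = seq.find(query)
            while start != -1:
                hits.append((name, start + 1))
                start = seq.find(query, start + 1)
        return hits

    def __contains__(self, query: str) -> bool:
        return any(query in seq for seq in self._records.values())


def read_proteome(path) -> Proteome:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    if not records:
        raise SchemaError(f"{path}: no FASTA records found")
    return Proteome(records)


def write_proteome(proteome: Proteome, path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in proteome.records.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# gene list and supplemental class II table
# ---------------------------------------------------------------------------

def read_gene_list(path) -> set[str]:
    """One gene name per line; deduplicated and whitespace-trimmed."""
    with open(path) as fh:
        genes = {line.strip() for line in fh if line.strip()}
    if not genes:
        warnings.warn(f"{path}: gene list is empty", stacklevel=2)
    return genes


@dataclass
class SupplementalRecord:
    median_ic50: float
    median_percentile: float


SUPPLEMENTAL_COLUMNS = ["ID", "Median IC50", "Median Percentile"]


def read_supplemental(path) -> dict[str, SupplementalRecord]:
    """TSV keyed by variant id with median class II binding summaries."""
    with open(path, newline="") as fh:
        lines = [line.rstrip("\n") for line in fh]
    if not lines:
        raise SchemaError(f"{path}: empty supplemental file")
    header = lines[0].split("\t")
    missing = [c for c in SUPPLEMENTAL_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    index = {name: i for i, name in enumerate(header)}
    out: dict[str, SupplementalRecord] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        cells = line.split("\t")
        vid = cells[index["ID"]]
        if vid in out:
            raise SchemaError(f"{path}:{lineno}: duplicate variant id {vid!r}")
        where = f"{path}:{lineno}"
        ic50 = _parse_float(cells[index["Median IC50"]], where=where)
        pct = _parse_float(cells[index["Median Percentile"]], where=where)
        if ic50 is None or pct is None:
            raise SchemaError(f"{where}: supplemental medians must be numeric")
        out[vid] = SupplementalRecord(median_ic50=ic50, median_percentile=pct)
    return out


def write_supplemental(records: dict[str, SupplementalRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(SUPPLEMENTAL_COLUMNS) + "\n")
        for vid, rec in records.items():
            fh.write(f"{vid}\t{fmt_number(rec.median_ic50, 3)}\t{fmt_number(rec.median_percentile, 2)}\n")
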