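"""Mutant-protein construction and MT/WT peptide enumeration.

A somatic variant is applied to each transcript's protein to obtain the
mutant protein, then every fixed-length window (register) that overlaps a
mutated residue is cut out.  For an interior single-residue substitution and
the class I lengths 8-11 this yields 8+9+10+11 = 38 distinct short
peptides.  Transcripts whose candidate peptide lists are identical are
grouped into transcript sets.

Coordinates are 1-based and intervals closed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ConsistencyError, SchemaError

VARIANT_CLASSES = ("missense", "inframe_ins", "inframe_del", "frameshift")
DEFAULT_LENGTHS = (8, 9, 10, 11)


@dataclass(frozen=True)
class VariantSpec:
    """A protein-level somatic variant with its DNA/RNA evidence.

    ``protein_pos`` is the 1-based index of the first altered residue;
    ``ref_aa``/``alt_aa`` are the replaced and replacement residue strings
    (``alt_aa`` empty for a pure deletion; both ignored in favour of
    ``novel_tail`` for frameshifts).
    """

    variant_id: str
    variant_class: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    dna_vaf: float
    rna_vaf: float
    rna_depth: int
    gene: str
    gene_expr: float

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise SchemaError(f"unknown variant class {self.variant_class!r}")
        if self.protein_pos < 1:
            raise SchemaError("protein_pos must be >= 1")
        for name in ("dna_vaf", "rna_vaf"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SchemaError(f"{name} must be in [0, 1], got {v}")
        if self.variant_class == "missense" and not (
            len(self.ref_aa) == len(self.alt_aa) == 1
        ):
            raise SchemaError("missense requires single-residue ref_aa and alt_aa")


@dataclass(frozen=True)
class TranscriptSpec:
    transcript_id: str
    protein_seq: str
    tsl: int | None
    biotype: str
    expression: float

    def __post_init__(self) -> None:
        if not self.protein_seq:
            raise SchemaError(f"transcript {self.transcript_id}: empty protein sequence")
        if self.tsl is not None and self.tsl < 1:
            raise SchemaError(f"transcript {self.transcript_id}: TSL must be >= 1")


@dataclass(frozen=True)
class PeptidePair:
    """A mutant peptide and (when defined) its same-coordinate WT partner.

    ``start`` is the 1-based window start in the mutant protein;
    ``mutated_positions`` are 1-based within the peptide.  ``wt_seq`` is
    present only for equal-length substitutions, where it differs from
    ``mt_seq`` exactly at the mutated positions; length-changing variants
    (in-frame indels, frameshifts) have no comparable WT window.
    """

    mt_seq: str
    wt_seq: str | None
    length: int
    start: int
    mutated_positions: tuple[int, ...]
    transcript_set_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.mt_seq) != self.length:
            raise SchemaError("mt_seq length disagrees with declared length")
        if not self.mutated_positions:
            raise SchemaError("peptide must contain at least one mutated position")
        if any(not (1 <= p <= self.length) for p in self.mutated_positions):
            raise SchemaError("mutated_positions outside the peptide")
        if self.wt_seq is not None:
            if len(self.wt_seq) != self.length:
                raise SchemaError("wt_seq must have the same length as mt_seq")
            diffs = tuple(
                i + 1 for i, (a, b) in enumerate(zip(self.mt_seq, self.wt_seq)) if a != b
            )
            if diffs != tuple(sorted(self.mutated_positions)):
                raise SchemaError("wt_seq must differ from mt_seq exactly at mutated_positions")


@dataclass
class TranscriptSet:
    set_id: str
    transcript_ids: list[str]
    peptides: list[PeptidePair] = field(default_factory=list)


def _check_ref(protein: str, variant: VariantSpec, transcript_id: str) -> None:
    lo = variant.protein_pos - 1
    observed = protein[lo : lo + len(variant.ref_aa)]
    if observed != variant.ref_aa:
        raise ConsistencyError(
            f"transcript {transcript_id}: reference residues {variant.ref_aa!r} do not "
            f"match protein ({observed!r}) at position {variant.protein_pos}"
        )


def mutate(
    transcript: TranscriptSpec, variant: VariantSpec, novel_tail: str | None = None
) -> tuple[str, tuple[int, ...]]:
    """Apply the variant; return (mutant protein, mutated 1-based positions)."""
    protein = transcript.protein_seq
    pos = variant.protein_pos
    if pos > len(protein):
        raise ConsistencyError(
            f"transcript {transcript.transcript_id}: protein_pos {pos} beyond "
            f"protein of length {len(protein)}"
        )
    if variant.variant_class == "frameshift":
        if novel_tail is None:
            raise ConsistencyError(
                f"transcript {transcript.transcript_id}: frameshift variant "
                f"{variant.variant_id} requires a novel tail"
            )
        tail = novel_tail.split("*", 1)[0]  # translation stops at the first stop codon
        mutant = protein[: pos - 1] + tail
        if len(mutant) < pos:
            raise ConsistencyError(
                f"transcript {transcript.transcript_id}: frameshift tail is empty "
                f"after stop-codon truncation"
            )
        return mutant, tuple(range(pos, len(mutant) + 1))

    _check_ref(protein, variant, transcript.transcript_id)
    mutant = protein[: pos - 1] + variant.alt_aa + protein[pos - 1 + len(variant.ref_aa) :]
    if not mutant:
        raise ConsistencyError(
            f"transcript {transcript.transcript_id}: variant deletes the whole protein"
        )
    if len(variant.ref_aa) == len(variant.alt_aa):
        positions = tuple(
            pos + i for i, (r, a) in enumerate(zip(variant.ref_aa, variant.alt_aa)) if r != a
        )
        if not positions:
            raise ConsistencyError(
                f"variant {variant.variant_id}: ref_aa equals alt_aa (silent at protein level)"
            )
    elif variant.alt_aa:
        positions = tuple(range(pos, pos + len(variant.alt_aa)))
    else:
        # pure deletion: mark the junction residue
        positions = (min(pos, len(mutant)),)
    return mutant, positions


def apply_variant(
    transcript: TranscriptSpec, variant: VariantSpec, novel_tail: str | None = None
) -> str:
    """Mutant protein sequence for one transcript (see :func:`mutate`)."""
    return mutate(transcript, variant, novel_tail)[0]


def enumerate_registers(
    protein_len: int, mutated_positions, lengths
) -> list[tuple[int, int]]:
    """All (start, length) windows fully inside the protein that cover at
    least one mutated position, ordered by length then start.

    A window length exceeding the protein contributes no windows.  For a
    single interior substitution at least ``length`` residues from both
    termini every register exists, so the count is the sum of the lengths
    (38 for lengths 8-11).
    """
    if not lengths:
        raise SchemaError("lengths must be non-empty")
    positions = sorted(set(mutated_positions))
    if not positions:
        raise SchemaError("mutated_positions must be non-empty")
    if positions[0] < 1 or positions[-1] > protein_len:
        raise SchemaError("mutated position outside the protein")
    windows: list[tuple[int, int]] = []
    for length in sorted(set(lengths)):
        if length > protein_len:
            continue
        # union of per-position start intervals [p - length + 1, p], clipped
        starts: set[int] = set()
        for p in positions:
            lo = max(1, p - length + 1)
            hi = min(p, protein_len - length + 1)
            starts.update(range(lo, hi + 1))
        windows.extend((s, length) for s in sorted(starts))
    return windows


def generate_candidates(
    variant: VariantSpec,
    transcripts,
    lengths=DEFAULT_LENGTHS,
    novel_tail: str | None = None,
) -> dict[str, list[PeptidePair]]:
    """Per-transcript MT/WT peptide pairs over all registers and lengths.

    Duplicate MT sequences within a transcript (possible when mutated
    positions cluster) are removed, keeping the first window in canonical
    (length, start) order.
    """
    out: dict[str, list[PeptidePair]] = {}
    paired = (
        variant.variant_class == "missense"
        or (
            variant.variant_class in ("inframe_ins", "inframe_del")
            and len(variant.ref_aa) == len(variant.alt_aa)
        )
    )
    for tx in transcripts:
        mutant, positions = mutate(tx, variant, novel_tail)
        pairs: list[PeptidePair] = []
        seen: set[str] = set()
        for start, length in enumerate_registers(len(mutant), positions, lengths):
            mt = mutant[start - 1 : start - 1 + length]
            if mt in seen:
                continue
            seen.add(mt)
            pep_positions = tuple(
                p - start + 1 for p in positions if start <= p <= start + length - 1
            )
            wt = tx.protein_seq[start - 1 : start - 1 + length] if paired else None
            pairs.append(
                PeptidePair(
                    mt_seq=mt,
                    wt_seq=wt,
                    length=length,
                    start=start,
                    mutated_positions=pep_positions,
                )
            )
        out[tx.transcript_id] = pairs
    return out


def group_transcript_sets(peptide_lists: dict[str, list[PeptidePair]]) -> list[TranscriptSet]:
    """Partition transcripts by identical candidate peptide lists.

    Equality is judged on the canonically sorted MT sequences.  Set ids are
    TS1, TS2, ... assigned by the lexicographically smallest member
    transcript id, so the grouping is invariant to input order.
    """
    if not peptide_lists:
        raise SchemaError("group_transcript_sets requires at least one transcript")
    by_key: dict[tuple[str, ...], list[str]] = {}
    for tid, pairs in peptide_lists.items():
        key = tuple(sorted(p.mt_seq for p in pairs))
        by_key.setdefault(key, []).append(tid)
    groups = sorted(by_key.values(), key=lambda tids: min(tids))
    sets: list[TranscriptSet] = []
    for i, tids in enumerate(groups, start=1):
        set_id = f"TS{i}"
        representative = min(tids)
        peptides = [replace(p, transcript_set_id=set_id) for p in peptide_lists[representative]]
        sets.append(TranscriptSet(set_id=set_id, transcript_ids=sorted(tids), peptides=peptides))
    return sets
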