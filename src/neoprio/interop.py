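"""Import of external candidate tables (NeoFox-style and arbitrary custom
TSVs) plus the group/sort/feature-selection and axis-transform semantics
used to explore them.

Cells are kept as raw text with a numeric parse recorded alongside, so no
information is lost to coercion; grouping partitions rows by a key column
and sorting orders rows within each group, electing the best row as the
group's representative.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import SchemaError

#: Curated NeoFox score columns shown by default when present (names only;
#: the vocabulary is version-dependent and import is schema-light).
NEOFOX_DEFAULT_COLUMNS = (
    "patientIdentifier",
    "gene",
    "mutation.mutatedXmer",
    "mutation.wildTypeXmer",
    "DAI_MHCI_bestAffinity",
    "Recognition_Potential_MHCI_9mer",
    "PRIME_best_score",
    "HEX_alignment_score_MHCI",
    "IEDB_Immunogenicity_MHCI",
    "Generator_rate_MHCI",
)


@dataclass
class CandidateTable:
    """External candidate rows: raw text plus a parallel numeric parse."""

    raw: pd.DataFrame
    numeric: pd.DataFrame
    provenance: str
    key_column: str | None = None
    visible_columns: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.raw)

    @property
    def columns(self) -> list[str]:
        return list(self.raw.columns)


def _read_tsv(path, provenance: str) -> CandidateTable:
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
    if not header_line:
        raise SchemaError(f"{path}: empty file")
    header = header_line.split("\t")
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise SchemaError(f"{path}: duplicate column name(s): {', '.join(dupes)}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.empty:
        raise SchemaError(f"{path}: no candidate rows")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    return CandidateTable(raw=raw, numeric=numeric, provenance=provenance)


def import_neofox(path) -> CandidateTable:
    """One candidate per row; all columns retained, the curated default
    subset (when present) flagged visible."""
    table = _read_tsv(path, provenance="neofox")
    table.visible_columns = tuple(c for c in NEOFOX_DEFAULT_COLUMNS if c in table.raw.columns)
    if not table.visible_columns:
        table.visible_columns = tuple(table.raw.columns)
    return table


_ASCENDING_PATTERN = re.compile(r"rank|ic50|affinity|percentile", re.IGNORECASE)


def _column_is_numeric(numeric: pd.DataFrame, raw: pd.DataFrame, column: str) -> bool:
    nonempty = raw[column] != ""
    return bool(nonempty.any()) and not numeric.loc[nonempty, column].isna().any()


@dataclass
class GroupedView:
    """Custom-module view: rows partitioned by a key, sorted in-group."""

    group_by: str
    sort_by: str
    display_features: tuple[str, ...]
    #: group key -> rows (raw text), best-first by the sort column
    groups: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def representatives(self) -> pd.DataFrame:
        reps = [frame.iloc[0] for frame in self.groups.values()]
        return pd.DataFrame(reps).reset_index(drop=True)

    def export(self, path) -> None:
        frames = []
        for key, frame in self.groups.items():
            frame = frame.copy()
            frame.insert(0, "__group__", key)
            frames.append(frame)
        pd.concat(frames).to_csv(path, sep="\t", index=False)


def import_custom(
    path,
    group_by: str,
    sort_by: str,
    display_features=None,
    ascending: bool | None = None,
) -> GroupedView:
    """Read any candidate TSV and build the grouped/sorted view.

    Sorting is numeric when every non-empty cell of the sort column parses
    as a number, lexicographic otherwise.  Default direction: ascending for
    rank/IC50/affinity/percentile-like column names (lower is better),
    descending otherwise (score-like, higher is better); override with
    ``ascending``.  Display features default to everything except the group
    and sort keys.
    """
    table = _read_tsv(path, provenance="custom")
    for column in (group_by, sort_by):
        if column not in table.raw.columns:
            raise SchemaError(f"{path}: no such column {column!r}")
    if display_features is None:
        display = tuple(c for c in table.raw.columns if c not in (group_by, sort_by))
    else:
        display = tuple(display_features)
        missing = [c for c in display if c not in table.raw.columns]
        if missing:
            raise SchemaError(f"{path}: no such column(s): {', '.join(missing)}")
    if ascending is None:
        ascending = bool(_ASCENDING_PATTERN.search(sort_by))

    use_numeric = _column_is_numeric(table.numeric, table.raw, sort_by)
    frame = table.raw.copy()
    sort_key = table.numeric[sort_by] if use_numeric else frame[sort_by]
    frame = frame.assign(__key__=sort_key)
    view = GroupedView(group_by=group_by, sort_by=sort_by, display_features=display)
    for key in sorted(frame[group_by].unique()):
        grp = frame[frame[group_by] == key].sort_values(
            by="__key__", ascending=ascending, kind="mergesort"
        )
        view.groups[key] = grp.drop(columns="__key__").reset_index(drop=True)
    return view


TRANSFORMS = ("identity", "log2", "log10", "neg_log10")


@dataclass
class AxisTransformResult:
    values: list[float]
    n_excluded: int
    excluded_indices: list[int] = field(default_factory=list)


def transform_axis(values, transform: str, range_limit=None) -> AxisTransformResult:
    """Transform scatter-axis values; non-finite results and out-of-range
    values are excluded and counted rather than raised."""
    if transform not in TRANSFORMS:
        raise SchemaError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")
    fns = {
        "identity": lambda x: x,
        "log2": math.log2,
        "log10": math.log10,
        "neg_log10": lambda x: -math.log10(x),
    }
    fn = fns[transform]
    kept: list[float] = []
    excluded: list[int] = []
    for i, x in enumerate(values):
        try:
            y = fn(float(x))
        except (ValueError, OverflowError):
            excluded.append(i)
            continue
        if not math.isfinite(y):
            excluded.append(i)
            continue
        if range_limit is not None:
            lo, hi = range_limit
            if not (lo <= y <= hi):
                excluded.append(i)
                continue
        kept.append(y)
    return AxisTransformResult(values=kept, n_excluded=len(excluded), excluded_indices=excluded)
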