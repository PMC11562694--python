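"""Reviewer evaluation state: accept/reject/review decisions, comments,
tallies, and lossless TSV export/reload.

Evaluations and comments travel in the Evaluation and Comment columns of
the aggregate report TSV; comments are backslash-escaped so tabs, newlines
and unicode survive the round-trip.  XLSX export is one-way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .config import EVALUATIONS
from .errors import SchemaError
from .io_formats import (
    AggregateReportRow,
    read_aggregate_report,
    write_aggregate_report,
)

TRACKED = ("Accept", "Reject", "Review")  # Pending is the untracked default


@dataclass
class SessionState:
    """Per-variant evaluation + comment, with always-consistent tallies."""

    states: dict[str, tuple[str, str]] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, rows: list[AggregateReportRow]) -> "SessionState":
        return cls(states={row.variant_id: (row.evaluation, row.comment) for row in rows})

    def set_evaluation(self, variant_id: str, value: str, comment: str | None = None) -> None:
        if variant_id not in self.states:
            raise SchemaError(f"unknown variant id {variant_id!r}")
        if value not in EVALUATIONS:
            raise SchemaError(f"unknown evaluation {value!r}; expected one of {EVALUATIONS}")
        old_comment = self.states[variant_id][1]
        self.states[variant_id] = (value, old_comment if comment is None else comment)

    def tally(self) -> dict[str, int]:
        counts = {value: 0 for value in TRACKED}
        for evaluation, _ in self.states.values():
            if evaluation in counts:
                counts[evaluation] += 1
        return counts


def export_session(
    rows: list[AggregateReportRow], state: SessionState, path, fmt: str = "tsv"
) -> None:
    """Write the report with the session's evaluations/comments embedded."""
    unknown = sorted(set(state.states) - {r.variant_id for r in rows})
    if unknown:
        raise SchemaError(f"session holds unknown variant id(s): {', '.join(unknown)}")
    for row in rows:
        if row.variant_id in state.states:
            row.evaluation, row.comment = state.states[row.variant_id]
    write_aggregate_report(rows, path, fmt=fmt)


def reload_session(path) -> tuple[list[AggregateReportRow], SessionState]:
    """Reload a TSV session export; evaluations default to Pending when the
    column is absent.  XLSX files cannot be reloaded."""
    text_path = str(path)
    if text_path.lower().endswith(".xlsx"):
        raise SchemaError("xlsx exports are one-way; reload requires the tsv format")
    rows = read_aggregate_report(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if "Evaluation" not in header:
        warnings.warn(
            f"{path}: no Evaluation column; all evaluations reset to Pending",
            stacklevel=2,
        )
    return rows, SessionState.from_rows(rows)
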