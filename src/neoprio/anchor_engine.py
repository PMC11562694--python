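"""Anchor-probability profiles, anchor-position sets and anchor scenarios.

Each HLA allele / peptide length combination carries a normalized vector of
per-position probabilities that the position anchors the peptide to the MHC
groove (as opposed to facing the T-cell receptor).  The anchor-position set
is the smallest set of highest-probability positions covering a cumulative
mass threshold (default 0.8).  A candidate whose mutation sits entirely on
anchors while the wild-type peptide is itself a strong binder risks central
tolerance — the mutation is hidden from the TCR and the WT version has
already been presented — and is therefore deprioritized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import SchemaError
from .peptide_engine import PeptidePair
from .prediction_core import BindingSummary

VERDICTS = ("keep", "deprioritize", "not_applicable")


@dataclass(frozen=True)
class AnchorProfile:
    allele: str
    length: int
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.probabilities) != self.length:
            raise SchemaError(
                f"profile for {self.allele}/{self.length}: expected {self.length} "
                f"probabilities, got {len(self.probabilities)}"
            )
        if any(p < 0 for p in self.probabilities):
            raise SchemaError("anchor probabilities must be non-negative")
        if not math.isclose(sum(self.probabilities), 1.0, abs_tol=1e-6):
            raise SchemaError(
                f"profile for {self.allele}/{self.length}: probabilities sum to "
                f"{sum(self.probabilities)}, expected 1"
            )


@dataclass(frozen=True)
class AnchorScenario:
    mutation_at_anchor: bool
    wt_strong_binder: bool | None  # None when no WT partner exists
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise SchemaError(f"unknown verdict {self.verdict!r}")


def normalize_profile(allele: str, length: int, weights) -> AnchorProfile:
    """Scale non-negative weights to a probability vector summing to 1."""
    w = list(weights)
    if any(x < 0 for x in w):
        raise SchemaError("anchor weights must be non-negative")
    total = sum(w)
    if total == 0:
        raise SchemaError("anchor weights must not all be zero")
    return AnchorProfile(allele=allele, length=length, probabilities=tuple(x / total for x in w))


def anchor_positions(profile: AnchorProfile, mass_threshold: float = 0.8) -> set[int]:
    """Smallest highest-probability position set reaching the mass threshold.

    Positions are accumulated in order of decreasing probability, ties
    broken toward the smaller index, until the cumulative mass reaches the
    threshold; monotone in the threshold by construction.
    """
    if not (0 < mass_threshold <= 1):
        raise SchemaError("mass_threshold must be in (0, 1]")
    order = sorted(
        range(1, profile.length + 1), key=lambda i: (-profile.probabilities[i - 1], i)
    )
    chosen: set[int] = set()
    cumulative = 0.0
    for i in order:
        chosen.add(i)
        cumulative += profile.probabilities[i - 1]
        if cumulative >= mass_threshold - 1e-12:
            break
    return chosen


def classify_scenario(
    pair: PeptidePair,
    anchors: set[int],
    wt_median_ic50: float | None,
    binding_threshold: float = 500.0,
) -> AnchorScenario:
    """Anchor scenario of a candidate on one allele.

    Deprioritize only when every mutated position is an anchor position
    (the change is invisible to the TCR) AND the WT peptide is itself a
    strong binder (median IC50 at or below the binding threshold).  A pair
    without a WT partner (frameshift/indel) is not applicable.
    """
    if any(a < 1 or a > pair.length for a in anchors):
        raise SchemaError("anchor positions outside the peptide")
    mutation_at_anchor = set(pair.mutated_positions) <= set(anchors)
    if pair.wt_seq is None or wt_median_ic50 is None:
        return AnchorScenario(
            mutation_at_anchor=mutation_at_anchor,
            wt_strong_binder=None,
            verdict="not_applicable",
        )
    wt_strong = wt_median_ic50 <= binding_threshold
    verdict = "deprioritize" if (mutation_at_anchor and wt_strong) else "keep"
    return AnchorScenario(
        mutation_at_anchor=mutation_at_anchor, wt_strong_binder=wt_strong, verdict=verdict
    )


def select_heatmap_pairs(
    scored_pairs: list[tuple[PeptidePair, BindingSummary]],
    allele: str,
    cap: int = 15,
) -> list[tuple[PeptidePair, BindingSummary]]:
    """Top MT/WT pairs for one allele, for the anchor heatmap view.

    At most ``cap`` (default 15) pairs, ordered by ascending median MT IC50
    with ties broken by MT sequence lexicographic order.
    """
    relevant = [(p, s) for p, s in scored_pairs if s.allele == allele]
    relevant.sort(key=lambda item: (item[1].median_ic50_mt, item[0].mt_seq))
    return relevant[:cap]


# ---------------------------------------------------------------------------
# profile set + TSV round-trip (columns: allele, length, p1..pL)
# ---------------------------------------------------------------------------

class AnchorProfileSet:
    """Lookup table of anchor profiles keyed by (allele, length)."""

    def __init__(self, profiles=()):
        self._profiles: dict[tuple[str, int], AnchorProfile] = {}
        for p in profiles:
            self.add(p)

    def add(self, profile: AnchorProfile) -> None:
        key = (profile.allele, profile.length)
        if key in self._profiles:
            raise SchemaError(f"duplicate anchor profile for {key}")
        self._profiles[key] = profile

    def get(self, allele: str, length: int) -> AnchorProfile | None:
        return self._profiles.get((allele, length))

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self):
        return iter(self._profiles.values())


def read_anchor_profiles(path) -> AnchorProfileSet:
    profiles = AnchorProfileSet()
    with open(path) as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if not lines:
        raise SchemaError(f"{path}: empty anchor profile file")
    header = lines[0].split("\t")
    if header[:2] != ["allele", "length"]:
        raise SchemaError(f"{path}: header must start with 'allele\\tlength'")
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        allele = cells[0]
        try:
            length = int(cells[1])
            probs = tuple(float(c) for c in cells[2 : 2 + length])
        except (ValueError, IndexError):
            raise SchemaError(f"{path}:{lineno}: malformed anchor profile row") from None
        if len(probs) != length:
            raise SchemaError(f"{path}:{lineno}: expected {length} probabilities")
        profiles.add(AnchorProfile(allele=allele, length=length, probabilities=probs))
    return profiles


def write_anchor_profiles(profiles: AnchorProfileSet, path) -> None:
    max_len = max((p.length for p in profiles), default=0)
    with open(path, "w", newline="") as fh:
        fh.write("allele\tlength\t" + "\t".join(f"p{i}" for i in range(1, max_len + 1)) + "\n")
        for p in sorted(profiles, key=lambda q: (q.allele, q.length)):
            # repr keeps the vector lossless so the sum-to-1 invariant survives re-reading
            cells = [p.allele, str(p.length)] + [repr(x) for x in p.probabilities]
            fh.write("\t".join(cells) + "\n")
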