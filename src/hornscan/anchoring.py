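"""Chromosome anchoring of unplaced scaffolds by syntenic-alignment votes.

Each alignment record links an old, chromosome-anchored scaffold to an
interval of a new scaffold.  Votes are tallied per (new scaffold,
chromosome), weighted by aligned bases (raw old-scaffold counts are reported
alongside so the simpler counting rule can be audited), and the top
chromosome wins.  A strong runner-up triggers either a split-synteny flag --
the two chromosomes' intervals partition the scaffold spatially, the
signature of a fusion or chimera -- or an ambiguous verdict.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import pandas as pd

AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"
SPLIT_SYNTENY = "split_synteny"
MANUAL_OVERRIDE = "manual_override"

RECORD_COLUMNS = ["old_scaffold", "old_chrom", "new_scaffold", "new_start", "new_end"]


@dataclasses.dataclass(frozen=True)
class SyntenyVote:
    """Aggregate alignment support for one (new scaffold, chromosome)."""

    new_scaffold: str
    chromosome: str
    aligned_bases: int
    n_old_scaffolds: int
    intervals: tuple[tuple[int, int], ...]  # 0-based half-open on new scaffold


@dataclasses.dataclass(frozen=True)
class ChromosomeAssignment:
    new_scaffold: str
    chromosome: str  # a chromosome label, AMBIGUOUS, or UNASSIGNED
    confidence: float  # top aligned bases / total aligned bases
    flags: frozenset[str] = frozenset()
    original: str | None = None  # pre-override chromosome, if overridden


def tabulate_votes(records: pd.DataFrame) -> list[SyntenyVote]:
    """Aggregate alignment records into per-(scaffold, chromosome) votes."""
    if records.empty:
        return []
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"alignment summary lacks columns: {sorted(missing)}")
    votes = []
    grouped = records.groupby(["new_scaffold", "old_chrom"], sort=True)
    for (scaffold, chrom), grp in grouped:
        grp = grp.sort_values(["new_start", "new_end"])
        bases = int((grp["new_end"] - grp["new_start"]).sum())
        votes.append(
            SyntenyVote(
                new_scaffold=scaffold,
                chromosome=chrom,
                aligned_bases=bases,
                n_old_scaffolds=int(grp["old_scaffold"].nunique()),
                intervals=tuple(
                    (int(s), int(e))
                    for s, e in zip(grp["new_start"], grp["new_end"])
                ),
            )
        )
    return votes


def _interleaving_fraction(
    top: SyntenyVote, runner: SyntenyVote
) -> float:
    """Fraction of aligned bases violating the best spatial split.

    Considers every interval boundary as a split point and both orderings
    (top-first or runner-first); the minimum misplaced-base fraction over
    those splits measures how far the two chromosomes are from occupying
    disjoint halves of the scaffold.
    """
    pieces = [(s, e, "a") for s, e in top.intervals] + [
        (s, e, "b") for s, e in runner.intervals
    ]
    total = sum(e - s for s, e, _ in pieces)
    cuts = sorted({0} | {e for _, e, _ in pieces} | {s for s, _, _ in pieces})
    best = total
    for cut in cuts:
        for first in ("a", "b"):
            misplaced = 0
            for s, e, label in pieces:
                mid = (s + e) / 2
                before = mid < cut
                if (label == first) != before:
                    misplaced += e - s
            best = min(best, misplaced)
    return best / total if total else 0.0


def assign(
    votes: Sequence[SyntenyVote],
    ambiguity_ratio: float = 0.2,
    min_bases: int = 10_000,
    interleave_threshold: float = 0.1,
) -> ChromosomeAssignment:
    """Assign one scaffold's votes to a chromosome.

    Argmax by aligned bases; ties are ambiguous, sub-``min_bases`` support is
    unassigned.  When the runner-up holds more than ``ambiguity_ratio`` of
    the top's bases, the call is flagged ``split_synteny`` if the two
    chromosomes partition the scaffold spatially (interleaving below
    ``interleave_threshold``), otherwise the scaffold is ambiguous.
    """
    if not votes:
        return ChromosomeAssignment("", UNASSIGNED, 0.0)
    scaffold = votes[0].new_scaffold
    if any(v.new_scaffold != scaffold for v in votes):
        raise ValueError("assign expects votes for a single scaffold")
    ranked = sorted(votes, key=lambda v: (-v.aligned_bases, v.chromosome))
    total = sum(v.aligned_bases for v in ranked)
    top = ranked[0]
    if top.aligned_bases < min_bases:
        return ChromosomeAssignment(scaffold, UNASSIGNED, 0.0)
    confidence = top.aligned_bases / total
    if len(ranked) == 1:
        return ChromosomeAssignment(scaffold, top.chromosome, confidence)
    runner = ranked[1]
    if runner.aligned_bases == top.aligned_bases:
        return ChromosomeAssignment(scaffold, AMBIGUOUS, confidence)
    if runner.aligned_bases / top.aligned_bases > ambiguity_ratio:
        if _interleaving_fraction(top, runner) < interleave_threshold:
            return ChromosomeAssignment(
                scaffold, top.chromosome, confidence,
                flags=frozenset({SPLIT_SYNTENY}),
            )
        return ChromosomeAssignment(scaffold, AMBIGUOUS, confidence)
    return ChromosomeAssignment(scaffold, top.chromosome, confidence)


def assign_all(
    records: pd.DataFrame,
    ambiguity_ratio: float = 0.2,
    min_bases: int = 10_000,
) -> list[ChromosomeAssignment]:
    """Tabulate and assign every new scaffold in an alignment summary.

    Assignments are independent of input record order.
    """
    votes = tabulate_votes(records)
    by_scaffold: dict[str, list[SyntenyVote]] = {}
    for v in votes:
        by_scaffold.setdefault(v.new_scaffold, []).append(v)
    return [
        assign(vs, ambiguity_ratio=ambiguity_ratio, min_bases=min_bases)
        for _, vs in sorted(by_scaffold.items())
    ]


def apply_overrides(
    assignments: Sequence[ChromosomeAssignment],
    overrides: Mapping[str, str],
) -> list[ChromosomeAssignment]:
    """Apply manual chromosome overrides (e.g. cytogenetic evidence).

    Overridden entries carry the ``manual_override`` flag and preserve the
    original call; overrides naming unknown scaffolds warn and are ignored.
    """
    known = {a.new_scaffold for a in assignments}
    for scaffold in overrides:
        if scaffold not in known:
            warnings.warn(f"override for unknown scaffold {scaffold!r} ignored")
    out = []
    for a in assignments:
        if a.new_scaffold in overrides:
            out.append(
                ChromosomeAssignment(
                    a.new_scaffold,
                    overrides[a.new_scaffold],
                    a.confidence,
                    flags=a.flags | {MANUAL_OVERRIDE},
                    original=a.chromosome,
                )
            )
        else:
            out.append(a)
    return out


def assignments_frame(assignments: Iterable[ChromosomeAssignment]) -> pd.DataFrame:
    rows = [
        (
            a.new_scaffold,
            a.chromosome,
            a.confidence,
            ",".join(sorted(a.flags)),
            a.original or "",
        )
        for a in assignments
    ]
    return pd.DataFrame(
        rows,
        columns=["new_scaffold", "chromosome", "confidence", "flags", "original"],
    )
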