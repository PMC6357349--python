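"""Ingestion of precomputed per-position / per-allele score tables and BED tracks.

Conservation (e.g. vertebrate PhyloP), splicing z-scores (dPSI z) and similar
genome-track quantities enter the pipeline as tab-delimited extracts keyed by
position or by (position, ref, alt).  Annotation overlaps (TFBS and other
functional-region tracks) enter as BED files, each contributing one boolean
feature column.  Keys are used exactly as published; no strand normalisation
is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

MISSING = None  # sentinel for "no score for this key"


class ScoreTableError(ValueError):
    pass


@dataclass
class ScoreTable:
    """Exact-key score lookup, keyed by position or by allele.

    ``keying`` is ``"position"`` (contig, pos) or ``"allele"``
    (contig, pos, ref, alt); positions are 1-based as in the source TSVs.
    """

    name: str
    keying: str
    entries: dict[tuple, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class IntervalTrack:
    """Per-contig interval index over BED-style half-open intervals."""

    name: str
    trees: dict[str, IntervalTree] = field(default_factory=dict)
    n_intervals: int = 0

    @classmethod
    def from_intervals(
        cls, name: str, intervals: list[tuple[str, int, int]]
    ) -> "IntervalTrack":
        trees: dict[str, IntervalTree] = {}
        for contig, start, end in intervals:
            trees.setdefault(contig, IntervalTree()).addi(start, end)
        return cls(name=name, trees=trees, n_intervals=len(intervals))


def load_score_tsv(path: str, keying: str, name: str | None = None) -> ScoreTable:
    """Load a score TSV.

    Position tables have columns ``contig, pos, score``; allele tables have
    ``contig, pos, ref, alt, score``.  Positions are 1-based.  Duplicate keys
    and non-numeric scores are load errors.
    """
    if keying not in ("position", "allele"):
        raise ValueError(f"keying must be 'position' or 'allele', got {keying!r}")
    cols = (
        ["contig", "pos", "score"]
        if keying == "position"
        else ["contig", "pos", "ref", "alt", "score"]
    )
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
    if list(df.columns) != cols:
        raise ScoreTableError(
            f"{path}: expected columns {cols}, found {list(df.columns)}"
        )
    table = ScoreTable(name=name or path, keying=keying)
    for lineno, row in enumerate(df.itertuples(index=False), 2):
        try:
            score = float(row.score)
        except (TypeError, ValueError) as exc:
            raise ScoreTableError(f"{path}: line {lineno}: non-numeric score") from exc
        if score != score:  # NaN
            raise ScoreTableError(f"{path}: line {lineno}: non-finite score")
        key = (
            (str(row.contig), int(row.pos))
            if keying == "position"
            else (str(row.contig), int(row.pos), row.ref, row.alt)
        )
        if key in table.entries:
            raise ScoreTableError(f"{path}: line {lineno}: duplicate key {key}")
        table.entries[key] = score
    logger.info("%s: loaded %d score rows", path, len(table))
    return table


def lookup_position_score(table: ScoreTable, contig: str, pos: int) -> float | None:
    """Score at a 1-based position, or None when the key is absent."""
    if table.keying != "position":
        raise ScoreTableError(
            f"table {table.name} is keyed by {table.keying}, not position"
        )
    return table.entries.get((contig, pos), MISSING)


def lookup_allele_score(
    table: ScoreTable, contig: str, pos: int, ref: str, alt: str
) -> float | None:
    """Score for a (contig, pos, ref, alt) key, or None when absent."""
    if table.keying != "allele":
        raise ScoreTableError(
            f"table {table.name} is keyed by {table.keying}, not allele"
        )
    return table.entries.get((contig, pos, ref, alt), MISSING)


def in_track(track: IntervalTrack, contig: str, pos: int) -> bool:
    """True iff the 1-based position falls inside any interval of the track."""
    tree = track.trees.get(contig)
    if tree is None:
        return False
    return bool(tree.overlaps_point(pos - 1))
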