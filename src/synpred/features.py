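"""Sequence-derived features for synonymous variants.

Implements the splice-geometry features (distance to nearest splice site and
its exon-scaled forms), exonic-splicing-enhancer hexamer density, SR-protein
motif gain/loss, PWM-based splice-site scoring, CpG context, relative mRNA
position, relative synonymous codon usage (RSCU) and its variant-induced
change, and the tRNA-adaptation-index translation-efficiency feature.

Conventions that the upstream tool chain leaves implicit are fixed here and
documented on each function: distances count the exon-boundary base itself as
zero; transcript-terminal exon ends (which carry no splice site) are excluded
from the distance minimum whenever an internal boundary exists; the
translation-efficiency feature is the natural log of the alt-codon tAI weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genomic_io import (
    CODON_TABLE,
    CodingContext,
    GenomeSequence,
    Transcript,
    reverse_complement,
)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: amino acid -> list of sense codons (synonymous family)
SYNONYMOUS_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in CODON_TABLE.items():
    if _aa != "*":
        SYNONYMOUS_FAMILIES.setdefault(_aa, []).append(_codon)
SENSE_CODONS = sorted(c for c, a in CODON_TABLE.items() if a != "*")

# Wobble decoding at the anticodon's position 34 (pairing with the codon's
# third base).  Each codon third base maps to (anticodon wobble base, class);
# the first entry is the Watson-Crick decoder.  Default penalties follow the
# standard tAI convention (dos Reis-style s values).
WOBBLE_RULES: dict[str, list[tuple[str, str]]] = {
    "T": [("A", "WC"), ("G", "G:U")],
    "C": [("G", "WC"), ("A", "I:C")],
    "A": [("T", "WC"), ("A", "I:A")],
    "G": [("C", "WC"), ("T", "U:G")],
}
DEFAULT_WOBBLE_PENALTIES: dict[str, float] = {
    "WC": 0.0,
    "G:U": 0.41,
    "I:C": 0.28,
    "I:A": 0.9999,
    "U:G": 0.68,
}


@dataclass
class CodonUsageTable:
    """Observed codon counts; all 61 sense codons present (zeros allowed)."""

    counts: dict[str, float]

    def __post_init__(self) -> None:
        for codon in SENSE_CODONS:
            self.counts.setdefault(codon, 0.0)
        bad = [c for c in self.counts if c not in CODON_TABLE or CODON_TABLE[c] == "*"]
        if bad:
            raise ValueError(f"non-sense codons in usage table: {bad}")

    @classmethod
    def from_tsv(cls, path: str) -> "CodonUsageTable":
        return cls(_read_two_column_tsv(path))


@dataclass
class TrnaTable:
    """tRNA gene copy numbers by anticodon, with wobble-pairing penalties."""

    copies: dict[str, float]
    wobble_penalties: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WOBBLE_PENALTIES)
    )

    def __post_init__(self) -> None:
        if not any(v > 0 for v in self.copies.values()):
            raise ValueError("tRNA table has no anticodon with positive copy number")

    @classmethod
    def from_tsv(cls, path: str, wobble_penalties: dict[str, float] | None = None):
        copies = _read_two_column_tsv(path)
        kwargs = {}
        if wobble_penalties is not None:
            kwargs["wobble_penalties"] = wobble_penalties
        return cls(copies, **kwargs)


@dataclass
class MotifSet:
    """A hexamer list or a PWM collection used for splicing-motif features."""

    kind: str  # "hexamer-list" | "PWM"
    hexamers: frozenset[str] = frozenset()
    pwms: list[tuple[str, int, np.ndarray, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("hexamer-list", "PWM"):
            raise ValueError(f"unknown motif set kind {self.kind!r}")
        if self.kind == "hexamer-list":
            bad = [h for h in self.hexamers if len(h) != 6 or set(h) - set(_BASES)]
            if bad:
                raise ValueError(f"invalid hexamers: {bad[:5]}")

    @classmethod
    def from_hexamer_file(cls, path: str) -> "MotifSet":
        """One 6-mer per line; '#' starts a comment."""
        hexes = set()
        with open(path) as fh:
            for line in fh:
                token = line.split("#", 1)[0].strip().upper()
                if token:
                    hexes.add(token)
        return cls(kind="hexamer-list", hexamers=frozenset(hexes))


@dataclass
class SpliceModel:
    """Donor and acceptor log-odds matrices (rows A,C,G,T x width columns).

    ``donor_exonic``/``acceptor_exonic`` record how many of the leading
    columns are exonic (3 for a 9-wide donor, 20 intronic + 3 exonic for a
    23-wide acceptor in the usual layouts); they are metadata only — scoring
    slides each matrix over every window overlapping the variant.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    donor_exonic: int = 3
    acceptor_exonic: int = 3

    def __post_init__(self) -> None:
        for name, m in (("donor", self.donor), ("acceptor", self.acceptor)):
            m = np.asarray(m, dtype=float)
            if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
                raise ValueError(f"{name} matrix must be 4 x width>=1")
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)


def _read_two_column_tsv(path: str) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            key, value = fields[0].upper(), float(fields[1])
            if key in out:
                raise ValueError(f"{path}: line {lineno}: duplicate key {key}")
            out[key] = value
    return out


# ---------------------------------------------------------------------------
# splice geometry


def _splice_boundaries(ctx: CodingContext, transcript: Transcript) -> list[int]:
    """Genomic 0-based positions of the hosting exon's splice-site edge bases.

    The transcript's very first and very last exon edges abut no intron and
    are excluded when at least one internal boundary exists on the exon.
    """
    pos0 = ctx.variant.pos - 1
    gi = transcript.exon_index_genomic(pos0)
    if gi is None:
        raise ValueError(f"{ctx.variant.id}: not exonic in {transcript.id}")
    s, e = transcript.exons[gi]
    boundaries = []
    if gi > 0:
        boundaries.append(s)  # left edge splices to the upstream intron
    if gi < transcript.n_exons - 1:
        boundaries.append(e - 1)
    return boundaries


def dsp(ctx: CodingContext, transcript: Transcript) -> float | None:
    """Distance (nt) from the variant to the nearest splice site of its exon.

    The boundary base itself scores 0.  Single-exon transcripts have no
    splice site: the feature is missing (None) and is later zero-imputed.
    """
    boundaries = _splice_boundaries(ctx, transcript)
    if not boundaries:
        return None
    pos0 = ctx.variant.pos - 1
    return float(min(abs(pos0 - b) for b in boundaries))


def mde(ctx: CodingContext, transcript: Transcript) -> float | None:
    """Splice-site distance as a proportion of half the hosting exon length."""
    d = dsp(ctx, transcript)
    if d is None:
        return None
    return d / (ctx.exon_len / 2.0)


def dve(ctx: CodingContext, transcript: Transcript) -> float:
    """Position across the exon (5'→3' in transcript orientation) in [0, 1].

    0-based offset from the exon's 5' end divided by (exon_len - 1);
    a length-1 exon yields 0.
    """
    pos0 = ctx.variant.pos - 1
    gi = transcript.exon_index_genomic(pos0)
    s, e = transcript.exons[gi]
    offset = pos0 - s if transcript.strand == "+" else (e - 1) - pos0
    if ctx.exon_len == 1:
        return 0.0
    return offset / (ctx.exon_len - 1)


# ---------------------------------------------------------------------------
# sequence context


def cpg_context(ctx: CodingContext, genome: GenomeSequence) -> bool:
    """True iff the variant's reference position sits in a CG dinucleotide.

    Both reference dinucleotides containing the position ([pos-1, pos] and
    [pos, pos+1] on the genome's plus strand) are examined; at a contig edge
    only the existing neighbour is evaluated.
    """
    pos0 = ctx.variant.pos - 1
    seq = genome.contigs[ctx.variant.contig]
    left = seq[pos0 - 1 : pos0 + 1] if pos0 >= 1 else ""
    right = seq[pos0 : pos0 + 2]
    return left == "CG" or right == "CG"


def relative_mrna_position(ctx: CodingContext, transcript: Transcript) -> float:
    """CDS position of the variant as a fraction of CDS length, in (0, 1]."""
    return ctx.cds_pos / transcript.cds_length


# ---------------------------------------------------------------------------
# codon usage


def rscu_table(usage: CodonUsageTable) -> dict[str, float]:
    """Relative synonymous codon usage: count / mean count of the family.

    Single-codon families (Met, Trp) are defined as 1.0; a family whose total
    count is zero gets 0.0 for all members.
    """
    rscu: dict[str, float] = {}
    for _aa, family in SYNONYMOUS_FAMILIES.items():
        if len(family) == 1:
            rscu[family[0]] = 1.0
            continue
        total = sum(usage.counts[c] for c in family)
        if total == 0:
            for c in family:
                rscu[c] = 0.0
        else:
            mean = total / len(family)
            for c in family:
                rscu[c] = usage.counts[c] / mean
    return rscu


def delta_rscu(ctx: CodingContext, rscu: dict[str, float]) -> float:
    """RSCU(alt codon) - RSCU(ref codon); defined only for synonymous pairs."""
    if CODON_TABLE[ctx.ref_codon] != CODON_TABLE[ctx.alt_codon]:
        raise ValueError(
            f"delta_rscu undefined for non-synonymous change "
            f"{ctx.ref_codon}->{ctx.alt_codon}"
        )
    return rscu[ctx.alt_codon] - rscu[ctx.ref_codon]


# ---------------------------------------------------------------------------
# translation efficiency (tAI)


def tai_weights(trna: TrnaTable) -> dict[str, float]:
    """Per-codon tRNA adaptation weights in (0, 1].

    For each sense codon, W = sum over decoding anticodons (Watson-Crick plus
    the configured wobble classes) of (1 - s_class) * gene copies; w = W/max W.
    Codons with no decoder receive the geometric mean of the nonzero weights,
    the usual tAI fallback.
    """
    W: dict[str, float] = {}
    for codon in SENSE_CODONS:
        total = 0.0
        for wobble_base, cls in WOBBLE_RULES[codon[2]]:
            anticodon = wobble_base + reverse_complement(codon[:2])
            s = trna.wobble_penalties.get(cls)
            if s is None:
                continue
            total += (1.0 - s) * trna.copies.get(anticodon, 0.0)
        W[codon] = total
    wmax = max(W.values())
    if wmax <= 0:
        raise ValueError("no codon is decoded by any tRNA in the table")
    w = {c: v / wmax for c, v in W.items()}
    nonzero = [v for v in w.values() if v > 0]
    gmean = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    return {c: (v if v > 0 else gmean) for c, v in w.items()}


def te_feature(ctx: CodingContext, weights: dict[str, float], delta: bool = False) -> float:
    """Translation-efficiency feature: ln w(alt codon).

    With ``delta=True`` returns ln w(alt) - ln w(ref), the variant-induced
    change in log adaptation weight.
    """
    value = math.log(weights[ctx.alt_codon])
    if delta:
        value -= math.log(weights[ctx.ref_codon])
    return value


# ---------------------------------------------------------------------------
# splice-site PWM scoring


def score_pwm(matrix: np.ndarray, window: str) -> float:
    """Sum of per-column log-odds for a window (must match matrix width)."""
    if len(window) != matrix.shape[1]:
        raise ValueError("window length does not match matrix width")
    total = 0.0
    for j, base in enumerate(window):
        if base not in _BASE_INDEX:
            return float("-inf")  # N or other ambiguity cannot be scored
        total += matrix[_BASE_INDEX[base], j]
    return total


def max_splice_site_score(
    ctx: CodingContext,
    transcript: Transcript,
    genome: GenomeSequence,
    model: SpliceModel,
    use_alt: bool = False,
) -> float | None:
    """Maximum donor/acceptor PWM score over all windows covering the variant.

    Windows are taken on the coding strand of the genomic sequence (introns
    included, since splice motifs straddle exon boundaries).  With
    ``use_alt`` the alt base replaces the ref base before scoring.  Windows
    running off the contig are skipped; if every window is skipped the
    feature is missing.
    """
    pos0 = ctx.variant.pos - 1
    contig_seq = genome.contigs[ctx.variant.contig]
    best: float | None = None
    for matrix in (model.donor, model.acceptor):
        width = matrix.shape[1]
        for start in range(pos0 - width + 1, pos0 + 1):
            end = start + width
            if start < 0 or end > len(contig_seq):
                continue
            window = contig_seq[start:end]
            if use_alt:
                i = pos0 - start
                window = window[:i] + ctx.variant.alt + window[i + 1 :]
            if transcript.strand == "-":
                window = reverse_complement(window)
            score = score_pwm(matrix, window)
            if score == float("-inf"):
                continue
            if best is None or score > best:
                best = score
    return best


# ---------------------------------------------------------------------------
# ESE / SR motifs


def ese_density(exon_seq: str, motifs: MotifSet) -> float:
    """Fraction of length-6 windows of the exon that are ESE hexamers.

    Sequences shorter than 6 nt have no windows and score 0.
    """
    if motifs.kind != "hexamer-list":
        raise ValueError("ese_density requires a hexamer-list motif set")
    exon_seq = exon_seq.upper()
    n_windows = len(exon_seq) - 5
    if n_windows < 1:
        return 0.0
    hits = sum(
        1 for i in range(n_windows) if exon_seq[i : i + 6] in motifs.hexamers
    )
    return hits / n_windows


def _count_hits(window: str, motifs: MotifSet) -> int:
    if motifs.kind == "hexamer-list":
        return sum(
            1
            for i in range(len(window) - 5)
            if window[i : i + 6] in motifs.hexamers
        )
    hits = 0
    for _name, width, matrix, threshold in motifs.pwms:
        for i in range(len(window) - width + 1):
            if score_pwm(matrix, window[i : i + width]) >= threshold:
                hits += 1
    return hits


def motif_gain_loss(
    ref_window: str, alt_window: str, motifs: MotifSet
) -> tuple[int, int]:
    """(gained, lost) motif hits between equal-length ref/alt windows.

    Hits are hexamer memberships or PWM scores above threshold; the two
    windows must have equal length and differ at at most one position.
    """
    if len(ref_window) != len(alt_window):
        raise ValueError("ref and alt windows must have equal length")
    hits_ref = _count_hits(ref_window.upper(), motifs)
    hits_alt = _count_hits(alt_window.upper(), motifs)
    return max(hits_alt - hits_ref, 0), max(hits_ref - hits_alt, 0)


def variant_motif_windows(
    ctx: CodingContext,
    transcript: Transcript,
    genome: GenomeSequence,
    flank: int = 5,
) -> tuple[str, str]:
    """Coding-strand ref/alt windows of ±``flank`` nt around the variant.

    The window is truncated at the hosting exon's boundaries so only exonic
    sequence is scanned (11 nt by default, covering every hexamer that
    overlaps the variant).
    """
    pos0 = ctx.variant.pos - 1
    gi = transcript.exon_index_genomic(pos0)
    s, e = transcript.exons[gi]
    start = max(pos0 - flank, s)
    end = min(pos0 + flank + 1, e)
    ref_window = genome.fetch(ctx.variant.contig, start, end)
    i = pos0 - start
    alt_window = ref_window[:i] + ctx.variant.alt + ref_window[i + 1 :]
    if transcript.strand == "-":
        ref_window = reverse_complement(ref_window)
        alt_window = reverse_complement(alt_window)
    return ref_window, alt_window


def exon_sequence(
    ctx: CodingContext, transcript: Transcript, genome: GenomeSequence
) -> str:
    """Coding-strand sequence of the exon hosting the variant."""
    pos0 = ctx.variant.pos - 1
    gi = transcript.exon_index_genomic(pos0)
    s, e = transcript.exons[gi]
    seq = genome.fetch(ctx.variant.contig, s, e)
    return seq if transcript.strand == "+" else reverse_complement(seq)
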