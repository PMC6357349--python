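"""Genomic file I/O, transcript models, and coding-coordinate projection.

Internally all coordinates are 0-based half-open; the 1-based conventions of
FASTA headers' coordinates, GTF and VCF are converted once at parse time
(BED is already 0-based half-open).  User-facing :class:`Variant` positions
stay 1-based to match VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: sense codon -> one-letter amino acid; stops map to "*"
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


class FormatError(ValueError):
    """A file violated its declared format."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; ``*`` for a stop.

    Raises
    ------
    ValueError
        If the codon contains a base outside A/C/G/T (e.g. N).
    """
    codon = codon.upper()
    if codon not in CODON_TABLE:
        raise ValueError(f"ambiguous base in codon {codon!r}")
    return CODON_TABLE[codon]


@dataclass
class GenomeSequence:
    """Reference sequences keyed by contig name (uppercase DNA)."""

    contigs: dict[str, str]

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of ``[start, end)`` (0-based half-open), clipped to the contig."""
        seq = self.contigs[contig]
        return seq[max(start, 0) : min(end, len(seq))]

    def base(self, contig: str, pos1: int) -> str:
        """Single base at a 1-based position."""
        return self.contigs[contig][pos1 - 1]


@dataclass
class Transcript:
    """Strand-aware exon/CDS gene model.

    ``exons`` are 0-based half-open genomic intervals in ascending genomic
    order regardless of strand; ``cds_start``/``cds_end`` delimit the genomic
    CDS span (half-open).  Exon index 0 in *transcript* order is the 5'-most
    exon on the coding strand, i.e. the genomically last exon for minus-strand
    transcripts.
    """

    id: str
    gene: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for (s0, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"transcript {self.id}: overlapping exons")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def cds_intervals(self) -> list[tuple[int, int]]:
        """Exon pieces intersected with the CDS span, ascending genomic order."""
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return out

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals())

    def exon_index_genomic(self, pos0: int) -> int | None:
        """Index (genomic order) of the exon containing ``pos0``, or None."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos0 < e:
                return i
        return None

    def exon_index_transcript(self, pos0: int) -> int | None:
        """Exon index in transcript (5'→3') order."""
        gi = self.exon_index_genomic(pos0)
        if gi is None:
            return None
        return gi if self.strand == "+" else self.n_exons - 1 - gi

    def genomic_to_cds(self, pos0: int) -> int | None:
        """1-based CDS coordinate of genomic ``pos0``, or None if non-coding."""
        ivs = self.cds_intervals()
        offset = 0
        if self.strand == "+":
            for s, e in ivs:
                if s <= pos0 < e:
                    return offset + (pos0 - s) + 1
                offset += e - s
        else:
            for s, e in reversed(ivs):
                if s <= pos0 < e:
                    return offset + (e - 1 - pos0) + 1
                offset += e - s
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Genomic 0-based position of 1-based ``cds_pos``."""
        if not 1 <= cds_pos <= self.cds_length:
            raise ValueError(f"cds_pos {cds_pos} outside CDS of {self.id}")
        remaining = cds_pos - 1
        ivs = self.cds_intervals()
        if self.strand == "+":
            for s, e in ivs:
                if remaining < e - s:
                    return s + remaining
                remaining -= e - s
        else:
            for s, e in reversed(ivs):
                if remaining < e - s:
                    return e - 1 - remaining
                remaining -= e - s
        raise AssertionError("unreachable")

    def cds_sequence(self, genome: GenomeSequence) -> str:
        """Coding-strand CDS sequence."""
        parts = [genome.fetch(self.contig, s, e) for s, e in self.cds_intervals()]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)


@dataclass
class Variant:
    """A biallelic SNV; ``pos`` is 1-based genomic, per VCF."""

    contig: str
    pos: int
    ref: str
    alt: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.contig}:{self.pos}")

    @property
    def id(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class CodingContext:
    """A variant projected into codon space on its transcript's coding strand."""

    variant: Variant
    transcript_id: str
    cds_pos: int
    codon_index: int
    pos_in_codon: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    exon_index: int
    exon_len: int


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str) -> GenomeSequence:
    """Read a FASTA file into uppercase contig strings, order preserved."""
    contigs: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(path, "fasta"):
            if rec.id in contigs:
                raise FormatError(f"{path}: duplicate contig name {rec.id!r}")
            contigs[rec.id] = str(rec.seq).upper()
    except FormatError:
        raise
    except ValueError as exc:
        raise FormatError(f"{path}: line 1: {exc}") from exc
    return GenomeSequence(contigs)


def read_gtf(path: str) -> list[Transcript]:
    """Build transcript models from the exon and CDS rows of a GTF/GFF file.

    Transcripts whose CDS length is not a multiple of 3 are skipped with a
    warning, mirroring how incomplete annotations are usually handled.
    """
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse GTF/GFF: {exc}") from exc
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid_vals = feat.attributes.get("transcript_id")
        if not tid_vals:
            raise FormatError(f"{path}: {feat.featuretype} row missing transcript_id")
        tid = tid_vals[0]
        gene = (feat.attributes.get("gene_id") or [tid])[0]
        meta.setdefault(tid, (gene, feat.seqid, feat.strand))
        iv = (feat.start - 1, feat.end)  # GTF 1-based inclusive -> half-open
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)

    transcripts = []
    for tid, (gene, contig, strand) in meta.items():
        ex = sorted(exons.get(tid, []))
        cd = sorted(cds.get(tid, []))
        if not ex or not cd:
            logger.warning("transcript %s lacks exon or CDS rows; skipped", tid)
            continue
        tx = Transcript(
            id=tid,
            gene=gene,
            contig=contig,
            strand=strand,
            exons=ex,
            cds_start=cd[0][0],
            cds_end=cd[-1][1],
        )
        if tx.cds_length % 3 != 0:
            logger.warning(
                "transcript %s: CDS length %d not divisible by 3; skipped",
                tid,
                tx.cds_length,
            )
            continue
        transcripts.append(tx)
    return transcripts


def read_vcf(path: str) -> list[Variant]:
    """Read SNVs from a VCF; multiallelic rows are decomposed per alt allele.

    Indels and symbolic alleles are skipped (counted in a log message).
    """
    import cyvcf2

    variants: list[Variant] = []
    skipped = 0
    for rec in cyvcf2.VCF(path):
        for alt in rec.ALT:
            if len(rec.REF) == 1 and len(alt) == 1 and alt in "ACGT" and rec.REF in "ACGT":
                variants.append(Variant(rec.CHROM, rec.POS, rec.REF, alt))
            else:
                skipped += 1
    if skipped:
        logger.info("%s: skipped %d non-SNV alleles", path, skipped)
    return variants


def read_variant_tsv(path: str) -> list[Variant]:
    """Read labeled variants from a TSV with columns contig, pos, ref, alt, label."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = {"contig", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        label = getattr(row, "label", "unknown")
        out.append(Variant(str(row.contig), int(row.pos), row.ref, row.alt, label))
    return out


def read_bed(path: str):
    """Read a BED3+ file into an :class:`~synpred.external_scores.IntervalTrack`."""
    from .external_scores import IntervalTrack

    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start >= end")
            intervals.append((fields[0], start, end))
    import os

    return IntervalTrack.from_intervals(
        os.path.splitext(os.path.basename(path))[0], intervals
    )


# ---------------------------------------------------------------------------
# projection


def project_variant(
    variant: Variant, transcript: Transcript, genome: GenomeSequence
) -> CodingContext:
    """Project a genomic SNV into codon space on the transcript's coding strand.

    Raises
    ------
    ValueError
        If the position is intronic/UTR, or the stated ref allele does not
        match the genome.
    """
    pos0 = variant.pos - 1
    cds_pos = transcript.genomic_to_cds(pos0)
    if cds_pos is None:
        raise ValueError(
            f"{variant.id} not in CDS of transcript {transcript.id}"
        )
    genome_base = genome.base(variant.contig, variant.pos)
    if genome_base != variant.ref:
        raise ValueError(
            f"{variant.id}: ref {variant.ref} does not match genome base {genome_base}"
        )
    codon_index = (cds_pos - 1) // 3
    pos_in_codon = (cds_pos - 1) % 3
    cds_seq = transcript.cds_sequence(genome)
    ref_codon = cds_seq[codon_index * 3 : codon_index * 3 + 3]
    if transcript.strand == "+":
        alt_coding = variant.alt
    else:
        alt_coding = variant.alt.translate(_COMPLEMENT)
    alt_codon = (
        ref_codon[:pos_in_codon] + alt_coding + ref_codon[pos_in_codon + 1 :]
    )
    gi = transcript.exon_index_genomic(pos0)
    exon_len = transcript.exons[gi][1] - transcript.exons[gi][0]
    return CodingContext(
        variant=variant,
        transcript_id=transcript.id,
        cds_pos=cds_pos,
        codon_index=codon_index,
        pos_in_codon=pos_in_codon,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=translate_codon(ref_codon),
        alt_aa=translate_codon(alt_codon),
        exon_index=transcript.exon_index_transcript(pos0),
        exon_len=exon_len,
    )


def is_synonymous(ctx: CodingContext) -> bool:
    """True iff ref and alt codons encode the same amino acid (stop==stop)."""
    return translate_codon(ctx.ref_codon) == translate_codon(ctx.alt_codon)


def choose_canonical_transcript(
    variant: Variant, transcripts: Iterable[Transcript]
) -> Transcript:
    """Deterministically pick one transcript whose CDS contains the variant.

    Longest CDS wins; ties broken by lexicographically smallest transcript id.
    """
    pos0 = variant.pos - 1
    candidates = [
        t
        for t in transcripts
        if t.contig == variant.contig and t.genomic_to_cds(pos0) is not None
    ]
    if not candidates:
        raise ValueError(f"{variant.id}: no transcript with CDS containing position")
    return max(candidates, key=lambda t: (t.cds_length, _neg_lex(t.id)))


def _neg_lex(s: str) -> tuple[int, ...]:
    # invert lexicographic order so max() prefers the smaller id on CDS ties
    return tuple(-ord(c) for c in s)


def translate_cds(cds_seq: str) -> str:
    """Translate a coding-strand CDS (length divisible by 3) to amino acids."""
    return str(Seq(cds_seq).translate())
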