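"""Synthetic fixture generator: a toy genome with multi-exon genes, motif and
codon/tRNA resources, score tracks, and labeled synonymous variants with
controllable class signal.

The generator exists so that every pipeline stage — parsing, projection,
feature extraction, selection, training, evaluation — can be exercised
end-to-end without downloads.  Class signal is injected at the feature
level, not through a biological generative model: deleterious variants are
placed nearer splice sites and in ESE-dense exons, steered toward
low-adaptation synonymous codons, and given class-shifted simulated
conservation / splicing-z / TFBS tracks.  One simulated score column
(``noise``) carries no class signal at all, by construction.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import external_scores as xs
from . import features as ft
from . import genomic_io as gio
from .feature_matrix import ExtractorConfig

_BASES = "ACGT"

#: default simulated feature set (10 columns; `noise` is pure noise)
DEFAULT_SIM_FEATURES = [
    "dsp",
    "mde",
    "dve",
    "ese_dens",
    "mes",
    "tfbs",
    "ver_phylop",
    "dpsiz",
    "te",
    "noise",
]

#: simulated features that carry injected class signal
INFORMATIVE_SIM_FEATURES = [
    "dsp",
    "mde",
    "dve",
    "ese_dens",
    "tfbs",
    "ver_phylop",
    "dpsiz",
    "te",
]


@dataclass
class EffectSizes:
    """Per-feature class separation knobs (all zero -> no signal).

    dsp_decay: mean (nt) of the exponential splice-site distance drawn for
    deleterious variants (benign are uniform over the exon); 0 disables the
    placement bias.  cons_shift / dpsiz_shift: additive mean shifts of the
    simulated conservation and splicing z-score for the deleterious class
    (unit-variance normals).  tfbs_prob_pos/neg: probability that a
    deleterious / benign variant lies in a simulated TFBS interval.
    te_bias / ese_bias: probability that a deleterious variant takes the
    lowest-adaptation synonymous codon / an ESE-dense exon (benign take the
    complementary choice).
    """

    dsp_decay: float = 5.0
    cons_shift: float = 1.5
    dpsiz_shift: float = -1.5
    tfbs_prob_pos: float = 0.55
    tfbs_prob_neg: float = 0.15
    te_bias: float = 0.85
    ese_bias: float = 0.8

    @classmethod
    def null(cls) -> "EffectSizes":
        """No class signal on any channel."""
        return cls(
            dsp_decay=0.0,
            cons_shift=0.0,
            dpsiz_shift=0.0,
            tfbs_prob_pos=0.3,
            tfbs_prob_neg=0.3,
            te_bias=0.0,
            ese_bias=0.0,
        )


@dataclass
class SimConfig:
    """Study conditions of the synthetic benchmark.

    Defaults mirror a balanced 600-variant training set (300 deleterious,
    300 benign) over 30 multi-exon genes.
    """

    seed: int = 1
    n_genes: int = 30
    exons_per_gene: int = 4
    exon_len_range: tuple[int, int] = (60, 120)
    intron_len_range: tuple[int, int] = (80, 150)
    n_pos: int = 300
    n_neg: int = 300
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    missing_rate: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n_genes, self.exons_per_gene, self.n_pos, self.n_neg) < 1:
            raise ValueError("all counts must be >= 1")
        if self.exon_len_range[0] < 9:
            raise ValueError("exons shorter than 9 nt are infeasible")


@dataclass
class SimReference:
    genome: gio.GenomeSequence
    transcripts: list[gio.Transcript]
    ese_motifs: ft.MotifSet
    sr_motifs: ft.MotifSet
    usage: ft.CodonUsageTable
    trna: ft.TrnaTable
    splice_model: ft.SpliceModel


@dataclass
class SimDataset:
    config: SimConfig
    reference: SimReference
    variants: list[gio.Variant]
    position_tables: dict[str, xs.ScoreTable]
    allele_tables: dict[str, xs.ScoreTable]
    tracks: dict[str, xs.IntervalTrack]

    def extractor_config(self, features: list[str] | None = None) -> ExtractorConfig:
        ref = self.reference
        return ExtractorConfig(
            features=list(features or DEFAULT_SIM_FEATURES),
            ese_motifs=ref.ese_motifs,
            sr_motifs=ref.sr_motifs,
            splice_model=ref.splice_model,
            usage=ref.usage,
            trna=ref.trna,
            position_tables=self.position_tables,
            allele_tables=self.allele_tables,
            tracks=self.tracks,
        )


# ---------------------------------------------------------------------------
# reference


def _consensus_logodds(consensus: str, p_match: float = 0.7) -> np.ndarray:
    """4 x width log-odds matrix concentrated on a consensus string."""
    width = len(consensus)
    matrix = np.empty((4, width))
    p_other = (1.0 - p_match) / 3.0
    for j, base in enumerate(consensus):
        for i, b in enumerate(_BASES):
            p = p_match if b == base else p_other
            matrix[i, j] = math.log(p / 0.25)
    return matrix


def default_splice_model() -> ft.SpliceModel:
    """Synthetic donor (width 9) / acceptor (width 23) log-odds matrices
    built from canonical GT/AG consensus strings; a stand-in for externally
    supplied splice-site models."""
    donor = _consensus_logodds("CAGGTAAGT")
    acceptor = _consensus_logodds("T" * 16 + "TTNCAGG".replace("N", "T"))
    return ft.SpliceModel(donor=donor, acceptor=acceptor,
                          donor_exonic=3, acceptor_exonic=3)


def _random_hexamers(rng: np.random.Generator, n: int) -> frozenset[str]:
    hexes = set()
    while len(hexes) < n:
        hexes.add("".join(rng.choice(list(_BASES), size=6)))
    return frozenset(hexes)


def simulate_reference(config: SimConfig) -> SimReference:
    """Toy genome (one contig per gene), transcripts, motif/codon resources.

    Each gene has ``exons_per_gene`` exons whose union is exactly the CDS
    (adjusted so CDS length is divisible by 3 and free of stop codons);
    intron edges carry canonical GT/AG dinucleotides.  Half the genes are on
    the minus strand.
    """
    rng = np.random.default_rng(config.seed)
    sense_no_stop = [c for c in ft.SENSE_CODONS]
    contigs: dict[str, str] = {}
    transcripts: list[gio.Transcript] = []
    for g in range(config.n_genes):
        name = f"g{g:03d}"
        strand = "+" if g % 2 == 0 else "-"
        exon_lens = rng.integers(
            config.exon_len_range[0], config.exon_len_range[1] + 1,
            size=config.exons_per_gene,
        ).tolist()
        total = sum(exon_lens)
        exon_lens[-1] -= total % 3
        total = sum(exon_lens)
        n_codons = total // 3
        cds = "".join(rng.choice(sense_no_stop) for _ in range(n_codons))
        intron_lens = rng.integers(
            config.intron_len_range[0], config.intron_len_range[1] + 1,
            size=config.exons_per_gene - 1,
        ).tolist()
        flank = 60
        # genomic layout: flank exon (intron exon)* flank
        parts: list[str] = []
        exons: list[tuple[int, int]] = []
        pos = 0

        def _rand_seq(n: int) -> str:
            return "".join(rng.choice(list(_BASES), size=n))

        parts.append(_rand_seq(flank))
        pos += flank
        genomic_cds = cds if strand == "+" else gio.reverse_complement(cds)
        offset = 0
        for i, elen in enumerate(exon_lens):
            exons.append((pos, pos + elen))
            parts.append(genomic_cds[offset : offset + elen])
            offset += elen
            pos += elen
            if i < len(intron_lens):
                ilen = intron_lens[i]
                intron = _rand_seq(ilen)
                # canonical splice dinucleotides on the genomic plus strand
                if strand == "+":
                    intron = "GT" + intron[2:-2] + "AG"
                else:
                    intron = "CT" + intron[2:-2] + "AC"
                parts.append(intron)
                pos += ilen
        parts.append(_rand_seq(flank))
        contigs[name] = "".join(parts)
        transcripts.append(
            gio.Transcript(
                id=f"tx{g:03d}",
                gene=name,
                contig=name,
                strand=strand,
                exons=exons,
                cds_start=exons[0][0],
                cds_end=exons[-1][1],
            )
        )

    ese = _random_hexamers(rng, 80)
    sr = _random_hexamers(rng, 40)
    usage = ft.CodonUsageTable(
        {c: float(rng.integers(1, 100)) for c in ft.SENSE_CODONS}
    )
    copies = {}
    for c in ft.SENSE_CODONS:
        anticodon = gio.reverse_complement(c)
        copies[anticodon] = float(rng.integers(0, 13))
    if not any(v > 0 for v in copies.values()):  # pragma: no cover
        copies[next(iter(copies))] = 1.0
    trna = ft.TrnaTable(copies)
    return SimReference(
        genome=gio.GenomeSequence(contigs),
        transcripts=transcripts,
        ese_motifs=ft.MotifSet(kind="hexamer-list", hexamers=ese),
        sr_motifs=ft.MotifSet(kind="hexamer-list", hexamers=sr),
        usage=usage,
        trna=trna,
        splice_model=default_splice_model(),
    )


# ---------------------------------------------------------------------------
# variants


def _synonymous_alts(
    tx: gio.Transcript, genome: gio.GenomeSequence, pos0: int
) -> list[tuple[str, str]]:
    """(alt base, alt codon) pairs making a synonymous change at pos0."""
    ref = genome.contigs[tx.contig][pos0]
    out = []
    for alt in _BASES:
        if alt == ref:
            continue
        variant = gio.Variant(tx.contig, pos0 + 1, ref, alt)
        ctx = gio.project_variant(variant, tx, genome)
        if gio.is_synonymous(ctx):
            out.append((alt, ctx.alt_codon))
    return out


def simulate_variants(
    config: SimConfig, reference: SimReference
) -> list[gio.Variant]:
    """Labeled synonymous SNVs with class-conditional placement.

    Deleterious variants are drawn near splice sites (exponential distance,
    mean ``dsp_decay``), preferentially in ESE-dense exons, and steered
    toward the synonymous codon with the lowest tRNA-adaptation weight;
    benign variants are uniform over exon positions and take the
    highest-adaptation codon.  All emitted variants are synonymous by
    construction (rejection sampling).
    """
    rng = np.random.default_rng(config.seed + 101)
    eff = config.effect_sizes
    weights = ft.tai_weights(reference.trna)
    genome = reference.genome
    txs = reference.transcripts

    # per-transcript exon ESE densities for the placement bias
    densities: dict[str, list[float]] = {}
    for tx in txs:
        dens = []
        for s, e in tx.exons:
            seq = genome.fetch(tx.contig, s, e)
            if tx.strand == "-":
                seq = gio.reverse_complement(seq)
            dens.append(ft.ese_density(seq, reference.ese_motifs))
        densities[tx.id] = dens

    variants: list[gio.Variant] = []
    seen: set[tuple[str, int, str]] = set()
    for label, count in (("deleterious", config.n_pos), ("benign", config.n_neg)):
        deleterious = label == "deleterious"
        placed = 0
        attempts = 0
        max_attempts = 400 * count
        while placed < count:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not place {count} {label} variants in "
                    f"{max_attempts} attempts"
                )
            tx = txs[rng.integers(len(txs))]
            dens = densities[tx.id]
            if deleterious and eff.ese_bias > 0 and rng.random() < eff.ese_bias:
                order = np.argsort(dens)[::-1]
                gi = int(order[rng.integers(max(1, len(order) // 2))])
            else:
                gi = int(rng.integers(tx.n_exons))
            s, e = tx.exons[gi]
            elen = e - s
            if deleterious and eff.dsp_decay > 0:
                d = int(min(rng.exponential(eff.dsp_decay), elen - 1))
                boundaries = []
                if gi > 0:
                    boundaries.append(s + d)
                if gi < tx.n_exons - 1:
                    boundaries.append(e - 1 - d)
                if not boundaries:
                    continue
                pos0 = int(boundaries[rng.integers(len(boundaries))])
            else:
                pos0 = int(s + rng.integers(elen))
            alts = _synonymous_alts(tx, genome, pos0)
            if not alts:
                continue
            if deleterious:
                pick_extreme = rng.random() < eff.te_bias
                key = min if pick_extreme else None
            else:
                pick_extreme = rng.random() < eff.te_bias
                key = max if pick_extreme else None
            if key is not None:
                alt, _codon = key(alts, key=lambda ac: weights[ac[1]])
            else:
                alt, _codon = alts[rng.integers(len(alts))]
            ref = genome.contigs[tx.contig][pos0]
            sig = (tx.contig, pos0 + 1, alt)
            if sig in seen:
                continue
            seen.add(sig)
            variants.append(gio.Variant(tx.contig, pos0 + 1, ref, alt, label))
            placed += 1
    return variants


# ---------------------------------------------------------------------------
# score tables and tracks


def simulate_score_tables(
    config: SimConfig, variants: list[gio.Variant]
) -> tuple[dict[str, xs.ScoreTable], dict[str, xs.ScoreTable], dict[str, xs.IntervalTrack]]:
    """Class-shifted conservation / splicing-z score tables, a pure-noise
    score table, and a TFBS interval track enriched for the deleterious
    class.  A ``missing_rate`` fraction of keys is omitted from each score
    table to exercise downstream zero-imputation."""
    rng = np.random.default_rng(config.seed + 202)
    eff = config.effect_sizes
    phylop = xs.ScoreTable(name="ver_phylop", keying="position")
    noise = xs.ScoreTable(name="noise", keying="position")
    dpsiz = xs.ScoreTable(name="dpsiz", keying="allele")
    tfbs_intervals: list[tuple[str, int, int]] = []
    for v in variants:
        deleterious = v.label == "deleterious"
        cons = rng.normal(eff.cons_shift if deleterious else 0.0, 1.0)
        nz = rng.normal(0.0, 1.0)
        dz = rng.normal(eff.dpsiz_shift if deleterious else 0.0, 1.0)
        p_tfbs = eff.tfbs_prob_pos if deleterious else eff.tfbs_prob_neg
        in_tfbs = rng.random() < p_tfbs
        if rng.random() >= config.missing_rate:
            phylop.entries.setdefault((v.contig, v.pos), round(cons, 4))
        if rng.random() >= config.missing_rate:
            noise.entries.setdefault((v.contig, v.pos), round(nz, 4))
        if rng.random() >= config.missing_rate:
            dpsiz.entries[(v.contig, v.pos, v.ref, v.alt)] = round(dz, 4)
        if in_tfbs:
            half = int(rng.integers(3, 9))
            tfbs_intervals.append((v.contig, max(v.pos - 1 - half, 0), v.pos + half))
    track = xs.IntervalTrack.from_intervals("tfbs", tfbs_intervals)
    return {"ver_phylop": phylop, "noise": noise}, {"dpsiz": dpsiz}, {"tfbs": track}


def simulate_dataset(config: SimConfig | None = None) -> SimDataset:
    """Full synthetic benchmark: reference + variants + score resources."""
    config = config or SimConfig()
    reference = simulate_reference(config)
    variants = simulate_variants(config, reference)
    pos_tables, allele_tables, tracks = simulate_score_tables(config, variants)
    return SimDataset(config, reference, variants, pos_tables, allele_tables, tracks)


# ---------------------------------------------------------------------------
# file output


def write_dataset(data: SimDataset, out_dir: str) -> dict[str, str]:
    """Write the dataset in the exact formats the pipeline reads.

    Returns a mapping of logical name -> path (genome FASTA, gene-model GTF,
    variant VCF, label TSV, hexamer lists, codon-usage and tRNA TSVs, score
    TSVs, TFBS BED, and donor/acceptor PWM text files).
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    genome = data.reference.genome
    with open(_p("genome.fa"), "w") as fh:
        for contig, seq in genome.contigs.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    with open(_p("genes.gtf"), "w") as fh:
        for tx in data.reference.transcripts:
            attrs = f'gene_id "{tx.gene}"; transcript_id "{tx.id}";'
            for s, e in tx.exons:
                fh.write(
                    f"{tx.contig}\tsim\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            for s, e in tx.cds_intervals():
                fh.write(
                    f"{tx.contig}\tsim\tCDS\t{s + 1}\t{e}\t.\t{tx.strand}\t0\t{attrs}\n"
                )

    with open(_p("variants.vcf"), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, seq in genome.contigs.items():
            fh.write(f"##contig=<ID={contig},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(data.variants, key=lambda v: (v.contig, v.pos, v.alt)):
            fh.write(f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")

    with open(_p("labels.tsv"), "w") as fh:
        fh.write("contig\tpos\tref\talt\tlabel\n")
        for v in sorted(data.variants, key=lambda v: (v.contig, v.pos, v.alt)):
            fh.write(f"{v.contig}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.label}\n")

    for name, motifs in (
        ("ese_hexamers.txt", data.reference.ese_motifs),
        ("sr_hexamers.txt", data.reference.sr_motifs),
    ):
        with open(_p(name), "w") as fh:
            for h in sorted(motifs.hexamers):
                fh.write(h + "\n")

    with open(_p("codon_usage.tsv"), "w") as fh:
        for codon in sorted(data.reference.usage.counts):
            fh.write(f"{codon}\t{data.reference.usage.counts[codon]:g}\n")
    with open(_p("trna_copies.tsv"), "w") as fh:
        for anticodon in sorted(data.reference.trna.copies):
            fh.write(f"{anticodon}\t{data.reference.trna.copies[anticodon]:g}\n")

    for name, table in data.position_tables.items():
        with open(_p(f"{name}.tsv"), "w") as fh:
            fh.write("contig\tpos\tscore\n")
            for (contig, pos), score in sorted(table.entries.items()):
                fh.write(f"{contig}\t{pos}\t{score:g}\n")
    for name, table in data.allele_tables.items():
        with open(_p(f"{name}.tsv"), "w") as fh:
            fh.write("contig\tpos\tref\talt\tscore\n")
            for (contig, pos, ref, alt), score in sorted(table.entries.items()):
                fh.write(f"{contig}\t{pos}\t{ref}\t{alt}\t{score:g}\n")

    for name, track in data.tracks.items():
        with open(_p(f"{name}.bed"), "w") as fh:
            rows = []
            for contig, tree in track.trees.items():
                rows.extend((contig, iv.begin, iv.end) for iv in tree)
            for contig, start, end in sorted(rows):
                fh.write(f"{contig}\t{start}\t{end}\n")

    model = data.reference.splice_model
    for name, matrix in (("donor", model.donor), ("acceptor", model.acceptor)):
        with open(_p(f"splice_{name}.pwm"), "w") as fh:
            fh.write(f"{name}\t{matrix.shape[1]}\n")
            for i, base in enumerate(_BASES):
                fh.write(base + "\t" + "\t".join(f"{x:.6f}" for x in matrix[i]) + "\n")
    return paths


def read_pwm(path: str) -> np.ndarray:
    """Read a PWM text block (name/width line, then 4 rows A/C/G/T)."""
    with open(path) as fh:
        header = fh.readline().split("\t")
        width = int(header[1])
        matrix = np.empty((4, width))
        for i, base in enumerate(_BASES):
            fields = fh.readline().rstrip("\n").split("\t")
            if fields[0] != base or len(fields) != width + 1:
                raise ValueError(f"{path}: malformed PWM row for base {base}")
            matrix[i] = [float(x) for x in fields[1:]]
    return matrix
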