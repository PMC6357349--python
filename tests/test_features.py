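"""Splice geometry, motif, codon-usage and tRNA-adaptation features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synpred import features as ft
from synpred.genomic_io import (
    CodingContext,
    GenomeSequence,
    Transcript,
    Variant,
    reverse_complement,
)


def make_tx(exons, strand="+", contig="c1", tid="t"):
    return Transcript(
        id=tid, gene="g", contig=contig, strand=strand,
        exons=exons, cds_start=exons[0][0], cds_end=exons[-1][1],
    )


def make_ctx(pos1, exon_len, contig="c1", ref="A", alt="G",
             ref_codon="GAA", alt_codon="GAG"):
    """Minimal coding context for geometry features (codons are dummies)."""
    return CodingContext(
        variant=Variant(contig, pos1, ref, alt),
        transcript_id="t", cds_pos=1, codon_index=0, pos_in_codon=0,
        ref_codon=ref_codon, alt_codon=alt_codon, ref_aa="E", alt_aa="E",
        exon_index=0, exon_len=exon_len,
    )


# ------------------------------------------------------------ splice geometry


class TestSpliceGeometry:
    # exon [1001..1100] 1-based = (1000, 1100) half-open; internal exon
    TX3 = make_tx([(900, 950), (1000, 1100), (1200, 1260)])

    def test_dsp_interior(self):
        assert ft.dsp(make_ctx(1005, 100), self.TX3) == 4

    def test_dsp_boundary_base_is_zero(self):
        assert ft.dsp(make_ctx(1001, 100), self.TX3) == 0
        assert ft.dsp(make_ctx(1100, 100), self.TX3) == 0

    def test_dsp_single_exon_missing(self):
        tx1 = make_tx([(1000, 1100)])
        assert ft.dsp(make_ctx(1005, 100), tx1) is None

    def test_dsp_terminal_exon_excludes_transcript_end(self):
        # first exon [901..950]: only its 3' edge (950) splices
        assert ft.dsp(make_ctx(902, 50), self.TX3) == 48

    def test_mde(self):
        assert ft.mde(make_ctx(1005, 100), self.TX3) == pytest.approx(0.08)
        assert ft.mde(make_ctx(1001, 100), self.TX3) == 0.0

    def test_mde_bounded_by_one_at_midpoint(self):
        tx = make_tx([(0, 10), (100, 201), (300, 310)])  # middle exon len 101
        mid = make_ctx(151, 101)
        assert ft.mde(mid, tx) <= 1.0

    def test_dve_plus_strand(self):
        assert ft.dve(make_ctx(1005, 100), self.TX3) == pytest.approx(4 / 99)
        assert ft.dve(make_ctx(1001, 100), self.TX3) == 0.0
        assert ft.dve(make_ctx(1100, 100), self.TX3) == 1.0

    def test_dve_minus_strand_counts_from_transcript_5prime(self):
        tx = make_tx([(900, 950), (1000, 1100), (1200, 1260)], strand="-")
        # on minus strand the exon's 5' end is its genomic right edge
        assert ft.dve(make_ctx(1100, 100), tx) == 0.0
        assert ft.dve(make_ctx(1001, 100), tx) == 1.0

    def test_geometry_invariant_under_coordinate_shift(self):
        shift = 10_000
        tx2 = make_tx([(s + shift, e + shift) for s, e in self.TX3.exons])
        for pos1 in (1001, 1005, 1050, 1100):
            a, b = make_ctx(pos1, 100), make_ctx(pos1 + shift, 100)
            assert ft.dsp(a, self.TX3) == ft.dsp(b, tx2)
            assert ft.mde(a, self.TX3) == ft.mde(b, tx2)
            assert ft.dve(a, self.TX3) == ft.dve(b, tx2)


# ----------------------------------------------------------- sequence context


class TestSequenceContext:
    def test_cpg_both_sides(self):
        genome = GenomeSequence({"c1": "ACGT"})
        assert ft.cpg_context(make_ctx(2, 4, ref="C", alt="T"), genome) is True
        assert ft.cpg_context(make_ctx(3, 4, ref="G", alt="A"), genome) is True

    def test_no_cpg(self):
        genome = GenomeSequence({"c1": "AATT"})
        for pos in range(1, 5):
            assert ft.cpg_context(make_ctx(pos, 4, ref="A", alt="G"), genome) is False

    def test_contig_edge(self):
        genome = GenomeSequence({"c1": "CGTT"})
        assert ft.cpg_context(make_ctx(1, 4, ref="C", alt="T"), genome) is True

    def test_relative_mrna_position(self):
        tx = make_tx([(0, 300)])
        ctx = make_ctx(1, 300)
        ctx.cds_pos = 1
        assert ft.relative_mrna_position(ctx, tx) == pytest.approx(1 / 300)
        ctx.cds_pos = 300
        assert ft.relative_mrna_position(ctx, tx) == 1.0
        tx6 = make_tx([(0, 6)])
        ctx.cds_pos = 3
        assert ft.relative_mrna_position(ctx, tx6) == 0.5


# --------------------------------------------------------------- codon usage


class TestRscu:
    def test_uniform_counts_all_one(self):
        usage = ft.CodonUsageTable({c: 7.0 for c in ft.SENSE_CODONS})
        assert all(v == pytest.approx(1.0) for v in ft.rscu_table(usage).values())

    def test_two_codon_family(self):
        usage = ft.CodonUsageTable({c: 0.0 for c in ft.SENSE_CODONS})
        usage.counts["GAA"], usage.counts["GAG"] = 30.0, 10.0
        rscu = ft.rscu_table(usage)
        assert rscu["GAA"] == pytest.approx(1.5)
        assert rscu["GAG"] == pytest.approx(0.5)

    def test_single_codon_family_is_one(self):
        usage = ft.CodonUsageTable({c: 0.0 for c in ft.SENSE_CODONS})
        usage.counts["ATG"] = 55.0
        rscu = ft.rscu_table(usage)
        assert rscu["ATG"] == 1.0 and rscu["TGG"] == 1.0

    def test_all_zero_family_is_zero(self):
        usage = ft.CodonUsageTable({c: 0.0 for c in ft.SENSE_CODONS})
        assert ft.rscu_table(usage)["GAA"] == 0.0

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 200), min_size=61, max_size=61))
    def test_family_sums_equal_family_size(self, counts):
        usage = ft.CodonUsageTable(dict(zip(ft.SENSE_CODONS, map(float, counts))))
        rscu = ft.rscu_table(usage)
        for family in ft.SYNONYMOUS_FAMILIES.values():
            if len(family) > 1 and sum(usage.counts[c] for c in family) > 0:
                assert sum(rscu[c] for c in family) == pytest.approx(len(family))

    def test_delta_rscu_antisymmetric(self):
        usage = ft.CodonUsageTable({c: 0.0 for c in ft.SENSE_CODONS})
        usage.counts["GAA"], usage.counts["GAG"] = 30.0, 10.0
        rscu = ft.rscu_table(usage)
        fwd = make_ctx(1, 10, ref_codon="GAA", alt_codon="GAG")
        rev = make_ctx(1, 10, ref="G", alt="A", ref_codon="GAG", alt_codon="GAA")
        assert ft.delta_rscu(fwd, rscu) == pytest.approx(-1.0)
        assert ft.delta_rscu(rev, rscu) == pytest.approx(1.0)

    def test_delta_rscu_rejects_nonsynonymous(self):
        rscu = ft.rscu_table(ft.CodonUsageTable({c: 1.0 for c in ft.SENSE_CODONS}))
        bad = make_ctx(1, 10, ref_codon="GAA", alt_codon="GAC")
        with pytest.raises(ValueError, match="non-synonymous"):
            ft.delta_rscu(bad, rscu)


# ------------------------------------------------------------------------ tAI


def _wc_only_table(copies):
    return ft.TrnaTable(copies, wobble_penalties={"WC": 0.0})


class TestTai:
    def test_two_decoders(self):
        trna = _wc_only_table(
            {reverse_complement("GAA"): 10.0, reverse_complement("GAG"): 5.0}
        )
        w = ft.tai_weights(trna)
        assert w["GAA"] == pytest.approx(1.0)
        assert w["GAG"] == pytest.approx(0.5)

    def test_zero_decoder_gets_geometric_mean(self):
        trna = _wc_only_table(
            {reverse_complement("GAA"): 10.0, reverse_complement("GAG"): 2.5}
        )
        w = ft.tai_weights(trna)
        assert w["GAG"] == pytest.approx(0.25)
        # any undecoded codon: geometric mean of {1.0, 0.25} = 0.5
        assert w["TTT"] == pytest.approx(0.5)

    def test_single_decoder_weight_one(self):
        w = ft.tai_weights(_wc_only_table({reverse_complement("GGC"): 4.0}))
        assert w["GGC"] == pytest.approx(1.0)

    def test_wobble_penalty_discounts_copies(self):
        # codon GAT (ends T): WC anticodon ATC, wobble G:U anticodon GTC
        trna = ft.TrnaTable(
            {"ATC": 0.0, "GTC": 10.0, "TTC": 10.0},
            wobble_penalties={"WC": 0.0, "G:U": 0.41},
        )
        w = ft.tai_weights(trna)
        # GAA (ends A) decoded WC by TTC: W=10; GAT decoded only via wobble: W=5.9
        assert w["GAT"] == pytest.approx(0.59)

    def test_weights_bounded_and_max_attained(self):
        rng = np.random.default_rng(0)
        copies = {
            reverse_complement(c): float(rng.integers(0, 10))
            for c in ft.SENSE_CODONS
        }
        if not any(copies.values()):
            copies["TTC"] = 1.0
        w = ft.tai_weights(ft.TrnaTable(copies))
        assert all(0 < v <= 1 for v in w.values())
        assert max(w.values()) == pytest.approx(1.0)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            ft.TrnaTable({"TTC": 0.0})

    def test_te_feature_log(self):
        w = {"GAG": 0.5, "GAA": 1.0}
        ctx = make_ctx(1, 10, ref_codon="GAA", alt_codon="GAG")
        assert ft.te_feature(ctx, w) == pytest.approx(math.log(0.5))
        assert ft.te_feature(ctx, {"GAG": 1.0, "GAA": 1.0}) == 0.0
        assert ft.te_feature(ctx, w, delta=True) == pytest.approx(math.log(0.5))


# ------------------------------------------------------------- splice scoring


class TestSpliceSiteScore:
    @pytest.fixture
    def model(self):
        donor = np.array(
            [
                [2.0, -1.0, -1.0],
                [-1.0, 2.0, -1.0],
                [-1.0, -1.0, 2.0],
                [-1.0, -1.0, -1.0],
            ]
        )  # consensus ACG, score 6.0
        acceptor = np.full((4, 4), -1.0)
        return ft.SpliceModel(donor=donor, acceptor=acceptor)

    def test_consensus_window_scores_column_max_sum(self, model):
        genome = GenomeSequence({"c1": "TTACGTT"})
        tx = make_tx([(0, 7)])
        ctx = make_ctx(4, 7, ref="C", alt="T")  # the C of ACG
        assert ft.max_splice_site_score(ctx, tx, genome, model) == pytest.approx(6.0)

    def test_max_dominates_single_windows(self, model):
        genome = GenomeSequence({"c1": "TTACGTT"})
        tx = make_tx([(0, 7)])
        ctx = make_ctx(4, 7, ref="C", alt="T")
        best = ft.max_splice_site_score(ctx, tx, genome, model)
        # every donor window overlapping pos 4 scores <= best
        for start in range(1, 4):
            w = genome.contigs["c1"][start : start + 3]
            assert ft.score_pwm(model.donor, w) <= best

    def test_use_alt_with_same_base_identical(self, model):
        genome = GenomeSequence({"c1": "TTACGTT"})
        tx = make_tx([(0, 7)])
        ctx = make_ctx(4, 7, ref="C", alt="C" if False else "T")
        ref_score = ft.max_splice_site_score(ctx, tx, genome, model, use_alt=False)
        ctx_same = make_ctx(4, 7, ref="C", alt="G")
        ctx_same.variant.alt = "C"  # alt equals the window base
        assert ft.max_splice_site_score(
            ctx_same, tx, genome, model, use_alt=True
        ) == pytest.approx(ref_score)

    def test_alt_substitution_changes_score(self, model):
        genome = GenomeSequence({"c1": "TTACGTT"})
        tx = make_tx([(0, 7)])
        ctx = make_ctx(4, 7, ref="C", alt="T")
        alt_score = ft.max_splice_site_score(ctx, tx, genome, model, use_alt=True)
        ref_score = ft.max_splice_site_score(ctx, tx, genome, model, use_alt=False)
        assert alt_score < ref_score

    def test_windows_off_contig_skipped(self, model):
        genome = GenomeSequence({"c1": "AC"})
        tx = make_tx([(0, 2)])
        ctx = make_ctx(1, 2, ref="A", alt="G")
        # width-3 and width-4 windows cannot fit in a 2 nt contig
        assert ft.max_splice_site_score(ctx, tx, genome, model) is None

    def test_minus_strand_scores_coding_orientation(self, model):
        # coding-strand ACG appears as CGT on the genomic plus strand
        genome = GenomeSequence({"c1": "TTCGTTT"})
        tx = make_tx([(0, 7)], strand="-")
        ctx = make_ctx(4, 7, ref="G", alt="A")
        assert ft.max_splice_site_score(ctx, tx, genome, model) == pytest.approx(6.0)


# ------------------------------------------------------------------ ESE / SR


class TestMotifs:
    def test_ese_density_window_count(self):
        motifs = ft.MotifSet(kind="hexamer-list", hexamers=frozenset({"GAAGAA"}))
        assert ft.ese_density("GAAGAAGAA", motifs) == pytest.approx(2 / 4)

    def test_ese_density_no_match_and_short(self):
        motifs = ft.MotifSet(kind="hexamer-list", hexamers=frozenset({"GAAGAA"}))
        assert ft.ese_density("TTTTTTTT", motifs) == 0.0
        assert ft.ese_density("GAAGA", motifs) == 0.0

    def test_ese_density_reversal_invariance_for_palindromic_set(self):
        pal = frozenset({"ACGTAC", "CATGCA"})
        closed = pal | {h[::-1] for h in pal}
        motifs = ft.MotifSet(kind="hexamer-list", hexamers=closed)
        rng = np.random.default_rng(11)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            assert ft.ese_density(seq, motifs) == ft.ese_density(seq[::-1], motifs)

    def test_snv_destroying_only_hit(self):
        motifs = ft.MotifSet(kind="hexamer-list", hexamers=frozenset({"GAAGAA"}))
        gained, lost = ft.motif_gain_loss("TGAAGAAT", "TGAAGCAT", motifs)
        assert (gained, lost) == (0, 1)

    def test_identical_windows(self):
        motifs = ft.MotifSet(kind="hexamer-list", hexamers=frozenset({"GAAGAA"}))
        assert ft.motif_gain_loss("TGAAGAAT", "TGAAGAAT", motifs) == (0, 0)

    def test_swap_symmetry(self):
        motifs = ft.MotifSet(kind="hexamer-list", hexamers=frozenset({"GAAGAA"}))
        g1, l1 = ft.motif_gain_loss("TGAAGAAT", "TGAAGCAT", motifs)
        g2, l2 = ft.motif_gain_loss("TGAAGCAT", "TGAAGAAT", motifs)
        assert (g1, l1) == (l2, g2)

    def test_length_mismatch_rejected(self):
        motifs = ft.MotifSet(kind="hexamer-list", hexamers=frozenset({"GAAGAA"}))
        with pytest.raises(ValueError, match="equal length"):
            ft.motif_gain_loss("GAAGAA", "GAAGA", motifs)

    def test_pwm_motif_counting(self):
        pwm = np.array(
            [[2.0, -9, -9], [-9, 2.0, -9], [-9, -9, 2.0], [-9, -9, -9]]
        )  # consensus ACG
        motifs = ft.MotifSet(kind="PWM", pwms=[("m", 3, pwm, 5.0)])
        gained, lost = ft.motif_gain_loss("TACGT", "TACTT", motifs)
        assert (gained, lost) == (0, 1)

    def test_variant_window_truncated_at_exon(self):
        genome = GenomeSequence({"c1": "A" * 30})
        tx = make_tx([(10, 20)])
        ctx = make_ctx(12, 10, ref="A", alt="G")  # pos0 11, one base into exon
        ref_w, alt_w = ft.variant_motif_windows(ctx, tx, genome)
        assert len(ref_w) == 7  # 1 left (exon start), self, 5 right
        assert alt_w.count("G") == 1

    def test_hexamer_file_parsing(self, tmp_path):
        p = tmp_path / "hex.txt"
        p.write_text("GAAGAA\n# comment\nacgtac  # inline\n")
        motifs = ft.MotifSet.from_hexamer_file(str(p))
        assert motifs.hexamers == frozenset({"GAAGAA", "ACGTAC"})
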