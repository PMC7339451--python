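"""The first-exon-skipping splicing model: junction prediction, reading
frame outcomes verified against translated toy sequences, and RNA junction
support."""

import pytest
from Bio.Seq import Seq

from fusionscreen.chimera import (
    FIVE_UTR_ONLY,
    IN_FRAME,
    NON_CODING,
    OUT_OF_FRAME,
    THREE_EXON1_UTR_ORF_INTACT,
    JunctionEvidence,
    frame_status,
    predict_chimera,
    verify_junction_support,
)
from fusionscreen.genome import GeneModel, GenomeAnnotation
from fusionscreen.svio import LEFT, RIGHT

from conftest import make_call, make_gene


def uib_call(toy, five="A", three="B", a_pos=30_000, distance=20_000):
    """5' breakpoint in intron 1 of the A-side gene, UIB upstream of the 3' gene."""
    b = toy.seq(three).model
    return make_call("S", "cA", a_pos, LEFT, "cB", b.tx_start - distance, RIGHT)


def translate_from_atg(transcript: str, atg_offset: int) -> str:
    coding = transcript[atg_offset:]
    coding = coding[: 3 * (len(coding) // 3)]
    return str(Seq(coding).translate())


class TestPredictChimera:
    def test_uib_junction_joins_exon1_to_exon2(self, chimera_toy):
        """Intronic 5' breakpoint + intergenic breakend 20 kb upstream of the
        3' gene: the junction joins the 5' gene's exon 1 to the 3' gene's
        exon 2, skipping the 3' gene's first exon."""
        pred = predict_chimera(uib_call(chimera_toy), chimera_toy.ann)
        assert pred is not None
        assert (pred.five_gene, pred.five_last_exon) == ("A", 1)
        assert (pred.three_gene, pred.three_first_exon) == ("B", 2)
        a, b = chimera_toy.seq("A").model, chimera_toy.seq("B").model
        assert pred.donor_pos == a.exons[0][1] - 1       # 3' boundary of A exon 1
        assert pred.acceptor_pos == b.exons[1][0]        # 5' boundary of B exon 2
        assert pred.uib_distance == 20_000

    def test_uib_acceptor_is_never_exon_one(self, chimera_toy):
        for three in ("B", "B2", "B3"):
            pred = predict_chimera(uib_call(chimera_toy, three=three), chimera_toy.ann)
            assert pred is not None and pred.three_first_exon == 2

    def test_gene_gene_acceptor_follows_breakpoint_intron(self):
        a = make_gene("A", "c1", "+", [(1_000, 1_100), (5_000, 5_100), (9_000, 9_100)],
                     cds=(1_050, 9_050))
        b = make_gene(
            "B", "c2", "+",
            [(10_000, 10_100), (20_000, 20_100), (30_000, 30_100), (40_000, 40_100), (50_000, 50_100)],
            cds=(10_050, 50_050),
        )
        ann = GenomeAnnotation([a, b], chrom_sizes={"c1": 100_000, "c2": 100_000})
        # B breakpoint in intron 3 -> acceptor is B exon 4
        call = make_call("S", "c1", 3_000, LEFT, "c2", 35_000, RIGHT)
        pred = predict_chimera(call, ann)
        assert (pred.five_gene, pred.five_last_exon) == ("A", 1)
        assert (pred.three_gene, pred.three_first_exon) == ("B", 4)
        assert pred.acceptor_pos == 40_000

    def test_discordant_orientation_returns_none(self, chimera_toy):
        b = chimera_toy.seq("B").model
        call = make_call("S", "cA", 30_000, LEFT, "cB", b.tx_start - 20_000, LEFT)
        assert predict_chimera(call, chimera_toy.ann) is None

    def test_exonic_five_breakpoint_returns_none(self, chimera_toy):
        b = chimera_toy.seq("B").model
        call = make_call("S", "cA", 1_050, LEFT, "cB", b.tx_start - 20_000, RIGHT)
        assert predict_chimera(call, chimera_toy.ann) is None

    def test_breakend_beyond_chimera_window_returns_none(self, chimera_toy):
        b = chimera_toy.seq("B").model
        call = make_call("S", "cA", 30_000, LEFT, "cB", b.tx_start - 150_000, RIGHT)
        assert predict_chimera(call, chimera_toy.ann, chimera_window=100_000) is None

    def test_strand_mirror_symmetry(self, chimera_toy):
        """Reversing both genes' strands and mirroring coordinates yields the
        mirrored junction."""
        L = 1_000_000
        mirrored = []
        for g in chimera_toy.ann.genes.values():
            exons = sorted((L - e, L - s) for s, e in g.exons)
            cds = (L - g.cds_end, L - g.cds_start) if g.is_coding else None
            mirrored.append(make_gene(g.gene_id, g.chrom, "-", exons, cds=cds))
        mann = GenomeAnnotation(mirrored, chrom_sizes={"cA": L, "cB": L})
        call = uib_call(chimera_toy)
        flip = {LEFT: RIGHT, RIGHT: LEFT}
        mcall = make_call(
            "S",
            call.bnd1.chrom, L - 1 - call.bnd1.pos, flip[call.bnd1.side],
            call.bnd2.chrom, L - 1 - call.bnd2.pos, flip[call.bnd2.side],
        )
        pred = predict_chimera(call, chimera_toy.ann)
        mpred = predict_chimera(mcall, mann)
        assert mpred is not None
        assert (mpred.five_gene, mpred.three_gene) == (pred.five_gene, pred.three_gene)
        assert mpred.donor_pos == L - 1 - pred.donor_pos
        assert mpred.acceptor_pos == L - 1 - pred.acceptor_pos
        assert mpred.uib_distance == pred.uib_distance


class TestFrameStatus:
    def test_three_exon1_utr_orf_intact(self, chimera_toy):
        """3' gene's first exon is untranslated: its ORF survives intact and
        the fusion transcript still encodes the full 3' protein."""
        pred = predict_chimera(uib_call(chimera_toy, three="B"), chimera_toy.ann)
        assert frame_status(pred, chimera_toy.ann) == THREE_EXON1_UTR_ORF_INTACT
        fusion = chimera_toy.fusion_transcript("A", 1, "B", 2)
        b = chimera_toy.seq("B")
        b_atg_in_fusion = fusion.index("ATGGCTCATCAT")
        assert translate_from_atg(fusion, b_atg_in_fusion) == "MAHHH*"
        assert translate_from_atg(b.transcript, b.transcript.index("ATGGCT")) == "MAHHH*"

    def test_five_utr_only_non_chimeric_protein(self, chimera_toy):
        """5' gene contributes only untranslated sequence: the protein is the
        3' gene's, not chimeric."""
        pred = predict_chimera(uib_call(chimera_toy, five="A2", a_pos=230_000, three="B"),
                               chimera_toy.ann)
        assert pred.five_gene == "A2"
        assert frame_status(pred, chimera_toy.ann) == FIVE_UTR_ONLY
        fusion = chimera_toy.fusion_transcript("A2", 1, "B", 2)
        assert translate_from_atg(fusion, fusion.index("ATGGCTCATCAT")) == "MAHHH*"

    def test_in_frame_join_preserves_three_prime_peptide(self, chimera_toy):
        """Retained 5' coding length (100 ≡ 1 mod 3) matches the 3' gene's
        skipped coding prefix (4 ≡ 1): the join is in frame and translation
        carries through to the 3' gene's stop codon."""
        pred = predict_chimera(uib_call(chimera_toy, three="B2"), chimera_toy.ann)
        assert frame_status(pred, chimera_toy.ann) == IN_FRAME
        fusion = chimera_toy.fusion_transcript("A", 1, "B2", 2)
        protein = translate_from_atg(fusion, fusion.index("ATGGCT"))
        assert protein == "M" + "A" * 33 + "HHH*"

    def test_out_of_frame_join_loses_three_prime_peptide(self, chimera_toy):
        """Skipped prefix 3 ≡ 0 mod 3 against retained 100 ≡ 1: frameshift;
        the 3' protein's peptide does not appear in the translation."""
        pred = predict_chimera(uib_call(chimera_toy, three="B3"), chimera_toy.ann)
        assert frame_status(pred, chimera_toy.ann) == OUT_OF_FRAME
        fusion = chimera_toy.fusion_transcript("A", 1, "B3", 2)
        protein = translate_from_atg(fusion, fusion.index("ATGGCT"))
        assert "HHH*" not in protein

    def test_mod3_arithmetic_example(self):
        # A retains 301 coding bp; B's skipped coding prefix is 1 bp: 301 ≡ 1 ≡ 1
        a = make_gene("A", "c1", "+", [(0, 400), (1_000, 1_100)], cds=(99, 1_050))
        b = make_gene("B", "c2", "+", [(0, 100), (1_000, 1_100)], cds=(99, 1_050))
        ann = GenomeAnnotation([a, b], chrom_sizes={"c1": 10_000, "c2": 10_000})
        call = make_call("S", "c1", 500, LEFT, "c2", 600, RIGHT)
        pred = predict_chimera(call, ann)
        assert (pred.five_last_exon, pred.three_first_exon) == (1, 2)
        assert a.coding_prefix_len(1) == 301
        assert b.coding_prefix_len(1) == 1
        assert frame_status(pred, ann) == IN_FRAME

    def test_non_coding_partner(self, toy_ann):
        from fusionscreen.chimera import ChimeraPrediction

        pred = ChimeraPrediction(
            five_gene="GA", five_last_exon=1, three_gene="GD", three_first_exon=2,
            donor_chrom="c1", donor_pos=10_199, acceptor_chrom="c2", acceptor_pos=800_099,
        )
        assert frame_status(pred, toy_ann) == NON_CODING


class TestJunctionSupport:
    def pred(self, chimera_toy):
        return predict_chimera(uib_call(chimera_toy), chimera_toy.ann)

    def test_three_reads_verify_two_do_not(self, chimera_toy):
        pred = self.pred(chimera_toy)
        ev3 = JunctionEvidence("S", [("cA", pred.donor_pos, "cB", pred.acceptor_pos, 3)])
        ev2 = JunctionEvidence("S", [("cA", pred.donor_pos, "cB", pred.acceptor_pos, 2)])
        assert verify_junction_support(pred, ev3) == (True, 3)
        assert verify_junction_support(pred, ev2) == (False, 2)

    def test_reads_sum_across_records(self, chimera_toy):
        pred = self.pred(chimera_toy)
        ev = JunctionEvidence("S", [
            ("cA", pred.donor_pos, "cB", pred.acceptor_pos, 2),
            ("cA", pred.donor_pos, "cB", pred.acceptor_pos, 2),
        ])
        assert verify_junction_support(pred, ev) == (True, 4)

    def test_offset_record_not_counted_at_zero_tolerance(self, chimera_toy):
        pred = self.pred(chimera_toy)
        ev = JunctionEvidence("S", [("cA", pred.donor_pos + 1, "cB", pred.acceptor_pos, 5)])
        assert verify_junction_support(pred, ev, tol=0) == (False, 0)
        assert verify_junction_support(pred, ev, tol=1) == (True, 5)
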