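import numpy as np
import pytest

from fusionviz import fixtures, protein_annotation
from fusionviz.fixtures import CODON_TABLE, translate_walk
from fusionviz.fusion_builder import FusionCandidate, FusionTranscript, build_fusion_transcript
from fusionviz.gene_models import TranscriptModel
from fusionviz.io_formats import DomainTableRow
from fusionviz.protein_annotation import (
    IN_FRAME,
    NO_CDS,
    OUT_OF_FRAME,
    FrameStatus,
    FusionProtein,
    determine_frame,
    remap_domains,
    translate_fusion,
)


def build_toy(rng, force_frame=None, strands=None):
    toy = fixtures.random_toy_fusion(rng, strands=strands, force_frame=force_frame)
    five, three = fixtures.toy_models(toy)
    cand = FusionCandidate(
        five_chrom=toy.gene5.chrom, five_pos=toy.bp5,
        five_strand=toy.gene5.strand, five_gene=toy.gene5.gene_name,
        three_chrom=toy.gene3.chrom, three_pos=toy.bp3,
        three_strand=toy.gene3.strand, three_gene=toy.gene3.gene_name,
    )
    ft = build_fusion_transcript(cand, five, three, toy.genome)
    return toy, ft


def three_frame_oracle(toy, ft):
    """Brute force: translate the cDNA in all 3 frames and ask which frame
    reproduces the 3' partner's native protein suffix; the fusion is in
    frame iff that frame is the 5' start codon's frame."""
    native3 = toy.gene3.native_protein()
    o = toy.s3 - toy.gene3.cds_spliced[0]
    lost = -(-o // 3)  # residues lost or cut by the junction
    suffix = native3[lost:]
    if len(suffix) < 5:
        return None  # too short to identify a frame unambiguously
    full = {
        f: "".join(
            CODON_TABLE.get(ft.cdna[i : i + 3], "X")
            for i in range(f, len(ft.cdna) - 2, 3)
        )
        for f in range(3)
    }
    start_frame = toy.gene5.cds_spliced[0] % 3
    return IN_FRAME if suffix in full[start_frame] else OUT_OF_FRAME


class TestDetermineFrame:
    def test_codon_boundary_in_frame(self, rng):
        for _ in range(10):
            toy, ft = build_toy(rng, force_frame="in_frame")
            fs = determine_frame(ft)
            assert fs.status == IN_FRAME
            assert fs.retained_five_cds % 3 == fs.three_cds_offset % 3

    def test_phase_shift_out_of_frame(self, rng):
        for _ in range(10):
            toy, ft = build_toy(rng, force_frame="out_of_frame")
            fs = determine_frame(ft)
            assert fs.status == OUT_OF_FRAME
            assert (fs.retained_five_cds - fs.three_cds_offset) % 3 != 0

    def test_agrees_with_three_frame_oracle(self, rng):
        for i in range(20):
            frame = "in_frame" if i % 2 == 0 else "out_of_frame"
            toy, ft = build_toy(rng, force_frame=frame)
            fs = determine_frame(ft)
            oracle = three_frame_oracle(toy, ft)
            if oracle is not None:
                assert fs.status == oracle

    def test_noncoding_five_partner(self, rng):
        toy, ft = build_toy(rng)
        ft.five_model.cds_span = None
        assert determine_frame(ft).status == NO_CDS

    def test_junction_in_five_utr(self, rng):
        # move the 5' breakpoint upstream of the start codon
        for _ in range(10):
            toy = fixtures.random_toy_fusion(rng)
            utr5 = toy.gene5.cds_spliced[0]
            if utr5 < 4:
                continue
            toy.s5 = utr5 - 2
            toy.bp5 = toy.gene5.spliced_to_genomic(toy.s5)
            five, three = fixtures.toy_models(toy)
            cand = FusionCandidate(
                five_chrom=toy.gene5.chrom, five_pos=toy.bp5,
                five_strand=toy.gene5.strand, five_gene="TOY5",
                three_chrom=toy.gene3.chrom, three_pos=toy.bp3,
                three_strand=toy.gene3.strand, three_gene="TOY3",
            )
            ft = build_fusion_transcript(cand, five, three, toy.genome)
            fs = determine_frame(ft)
            assert fs.status == NO_CDS and fs.reason == "junction_in_5'UTR"
            return
        pytest.skip("no toy with a long enough 5' UTR drawn")


class TestTranslateFusion:
    def test_in_frame_peptide_is_prefix_plus_suffix(self, rng):
        for _ in range(15):
            toy, ft = build_toy(rng, force_frame="in_frame")
            fs = determine_frame(ft)
            fp = translate_fusion(ft, fs)
            native5 = toy.gene5.native_protein()
            native3 = toy.gene3.native_protein()
            r5 = toy.s5 + 1 - toy.gene5.cds_spliced[0]
            lost3 = (toy.s3 - toy.gene3.cds_spliced[0]) // 3
            assert fp.peptide == native5[: r5 // 3] + native3[lost3:]
            assert fp.junction_aa == r5 // 3
            assert fp.c_terminus_source == "TOY3"

    def test_out_of_frame_truncates(self, rng):
        for _ in range(15):
            toy, ft = build_toy(rng, force_frame="out_of_frame")
            fs = determine_frame(ft)
            fp = translate_fusion(ft, fs)
            assert fp.c_terminus_source == "truncated"
            if fs.termination_cdna is not None:
                expected_len = (fs.termination_cdna - fs.translation_start_cdna) // 3
                assert len(fp.peptide) == expected_len

    def test_junction_aa_arithmetic(self, rng):
        toy, ft = build_toy(rng, force_frame="in_frame")
        fs = determine_frame(ft)
        fs.translation_start_cdna = 0
        ft.junction_offset = 30
        fp = translate_fusion(ft, fs)
        assert fp.junction_aa == 10

    def test_no_cds_refused(self, rng):
        toy, ft = build_toy(rng)
        with pytest.raises(ValueError):
            translate_fusion(ft, FrameStatus(NO_CDS))


def _dummy_model(tx, gene):
    return TranscriptModel(tx, gene, gene, "1", "+", exons=[(0, 3000)],
                          cds_span=(0, 3000))


class TestRemapDomains:
    five = _dummy_model("TX5", "GENEF")
    three = _dummy_model("TX3", "GENET")

    def make_fp(self, peptide_len, junction_aa):
        return FusionProtein(
            peptide="A" * peptide_len, junction_aa=junction_aa,
            n_terminus_source="GENEF", c_terminus_source="GENET",
        )

    def test_three_prime_shift_arithmetic(self):
        # 3' partner loses 100 aa (300 nt), junction at aa 40 (120 nt)
        fs = FrameStatus(IN_FRAME, retained_five_cds=120, three_cds_offset=300)
        fp = self.make_fp(400, 40)
        (dom,) = remap_domains(
            fp, fs, [DomainTableRow("TX3", "ETS", 290, 375)], self.five, self.three
        )
        assert (dom.start_aa, dom.end_aa) == (230, 315)
        assert dom.retained_fraction == 1.0

    def test_five_prime_clipping(self):
        fs = FrameStatus(IN_FRAME, retained_five_cds=105, three_cds_offset=0)
        fp = self.make_fp(400, 35)
        (dom,) = remap_domains(
            fp, fs, [DomainTableRow("TX5", "HLH", 10, 60)], self.five, self.three
        )
        assert (dom.start_aa, dom.end_aa) == (10, 35)
        assert dom.retained_fraction == pytest.approx(26 / 51)

    def test_out_of_frame_drops_three_prime_domains(self):
        fs = FrameStatus(OUT_OF_FRAME, retained_five_cds=121, three_cds_offset=300)
        fp = self.make_fp(100, 41)
        doms = remap_domains(
            fp, fs, [DomainTableRow("TX3", "ETS", 290, 375)], self.five, self.three
        )
        assert doms == []

    def test_fully_lost_domain_dropped(self):
        fs = FrameStatus(IN_FRAME, retained_five_cds=120, three_cds_offset=300)
        fp = self.make_fp(400, 40)
        doms = remap_domains(
            fp, fs, [DomainTableRow("TX3", "PNT", 10, 90)], self.five, self.three
        )
        assert doms == []  # ends at native aa 90 < 100 lost

    def test_unmatched_accession_warns_and_skips(self, caplog):
        fs = FrameStatus(IN_FRAME, retained_five_cds=120, three_cds_offset=0)
        fp = self.make_fp(100, 40)
        with caplog.at_level("WARNING"):
            doms = remap_domains(
                fp, fs, [DomainTableRow("TXZ", "X", 1, 10)], self.five, self.three
            )
        assert doms == [] and "neither" in caplog.text

    def test_residue_level_equivalence_on_random_placements(self, rng):
        """Remapped 3' domain substrings equal the native protein's."""
        checked = 0
        while checked < 12:
            toy, ft = build_toy(rng, force_frame="in_frame")
            fs = determine_frame(ft)
            fp = translate_fusion(ft, fs)
            native3 = toy.gene3.native_protein()
            lost3 = (toy.s3 - toy.gene3.cds_spliced[0]) // 3
            if len(native3) - lost3 < 5:
                continue
            a = int(rng.integers(1, len(native3) - 3))
            b = int(rng.integers(a, len(native3)))
            rows = [DomainTableRow(ft.three_model.transcript_id, "D", a, b)]
            doms = remap_domains(fp, fs, rows, ft.five_model, ft.three_model)
            if not doms:
                assert b <= lost3  # entirely lost
                continue
            (d,) = doms
            shift = (fs.retained_five_cds - fs.three_cds_offset) // 3
            native_start = d.start_aa - shift
            assert (
                fp.peptide[d.start_aa - 1 : d.end_aa]
                == native3[native_start - 1 : native_start - 1 + (d.end_aa - d.start_aa + 1)]
            )
            checked += 1
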