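import re

import numpy as np
import pandas as pd
import pysam
import pytest

from fusionviz import expression, io_formats
from fusionviz.expression import (
    compute_coverage,
    flag_fusion_positive,
    normalize_expression,
)
from fusionviz.gene_models import TranscriptModel
from fusionviz.io_formats import BedpeRecord, CountMatrix

REF = "ref"
REF_LEN = 3000

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def write_bam(path, reads):
    """reads: (qname, pos, cigar, flag, mapq) tuples on a single reference."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": REF, "LN": REF_LEN}]}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for qname, pos, cigar, flag, mapq in sorted(reads, key=lambda r: r[1]):
            a = pysam.AlignedSegment()
            a.query_name = qname
            qlen = sum(int(n) for n, op in _CIGAR_RE.findall(cigar)
                       if op in "MIS=X")
            a.query_sequence = "A" * qlen
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = cigar
            bam.write(a)
    pysam.index(str(path))
    return str(path)


def brute_force_depth(reads, lo, hi, mapq=0):
    """Independent pileup: expand each kept read's CIGAR by hand."""
    depth = np.zeros(hi - lo, dtype=int)
    for _, pos, cigar, flag, q in reads:
        if flag & (0x4 | 0x100 | 0x400 | 0x800) or q < mapq:
            continue
        ref = pos
        for n, op in _CIGAR_RE.findall(cigar):
            n = int(n)
            if op in "M=X":
                for p in range(ref, ref + n):
                    if lo <= p < hi:
                        depth[p - lo] += 1
                ref += n
            elif op in "DN":
                ref += n
    return depth


def model(span=(0, REF_LEN), exons=None):
    exons = exons or [span]
    return TranscriptModel("TX", "G", "G", REF, "+", exons=list(exons))


class TestComputeCoverage:
    def test_single_read_pileup(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", [("r1", 100, "50M", 0, 60)])
        tm = model(exons=[(90, 200)])
        track = compute_coverage(bam, tm, junction=120)
        expected = np.zeros(110, dtype=int)
        expected[10:60] = 1
        assert np.array_equal(track.depth, expected)

    def test_spliced_read_leaves_gap(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", [("r1", 100, "20M1000N20M", 0, 60)])
        tm = model(exons=[(0, 2000)])
        track = compute_coverage(bam, tm, junction=0)
        assert track.depth[100:120].tolist() == [1] * 20
        assert track.depth[120:1120].sum() == 0
        assert track.depth[1120:1140].tolist() == [1] * 20

    def test_clips_deletions_uncounted(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", [("r1", 100, "5S10M3D10M2S", 0, 60)])
        tm = model(exons=[(0, 300)])
        track = compute_coverage(bam, tm, junction=0)
        assert track.depth[100:110].tolist() == [1] * 10
        assert track.depth[110:113].sum() == 0  # deletion
        assert track.depth[113:123].tolist() == [1] * 10

    def test_duplicates_and_secondary_excluded(self, tmp_path):
        reads = [("r1", 100, "50M", 0, 60),
                 ("r1d", 100, "50M", 0x400, 60),
                 ("r1s", 100, "50M", 0x100, 60),
                 ("r1u", 100, "50M", 0x800, 60)]
        bam = write_bam(tmp_path / "a.bam", reads)
        track = compute_coverage(bam, model(exons=[(90, 200)]), junction=0)
        assert track.depth.max() == 1

    def test_mapq_threshold(self, tmp_path):
        reads = [("hi", 100, "50M", 0, 60), ("lo", 100, "50M", 0, 5)]
        bam = write_bam(tmp_path / "a.bam", reads)
        tm = model(exons=[(90, 200)])
        assert compute_coverage(bam, tm, 0, mapq=0).depth.max() == 2
        assert compute_coverage(bam, tm, 0, mapq=30).depth.max() == 1

    def test_empty_region_all_zero(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", [("r1", 100, "50M", 0, 60)])
        track = compute_coverage(bam, model(exons=[(2000, 2500)]), junction=0)
        assert track.depth.sum() == 0

    def test_absent_chromosome_errors(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", [("r1", 100, "50M", 0, 60)])
        tm = TranscriptModel("TX", "G", "G", "chrZ", "+", exons=[(0, 100)])
        with pytest.raises(ValueError, match="absent"):
            compute_coverage(bam, tm, junction=0)

    def test_matches_brute_force_on_random_bams(self, tmp_path, rng):
        """Pileup oracle: CIGAR-expansion agreement incl. N/S/D ops."""
        for case in range(6):
            reads = []
            for i in range(int(rng.integers(5, 30))):
                pos = int(rng.integers(0, 2000))
                kind = rng.integers(0, 4)
                if kind == 0:
                    cigar = f"{int(rng.integers(20, 60))}M"
                elif kind == 1:
                    cigar = (f"{int(rng.integers(10, 30))}M"
                             f"{int(rng.integers(50, 400))}N"
                             f"{int(rng.integers(10, 30))}M")
                elif kind == 2:
                    cigar = f"{int(rng.integers(3, 9))}S{int(rng.integers(20, 40))}M"
                else:
                    cigar = (f"{int(rng.integers(10, 20))}M"
                             f"{int(rng.integers(1, 5))}D"
                             f"{int(rng.integers(10, 20))}M")
                flag = int(rng.choice([0, 0, 0, 0x400, 0x100]))
                reads.append((f"c{case}r{i}", pos, cigar, flag, 60))
            bam = write_bam(tmp_path / f"r{case}.bam", reads)
            track = compute_coverage(bam, model(), junction=0)
            oracle = brute_force_depth(reads, 0, REF_LEN)
            assert np.array_equal(track.depth, oracle)
            # total depth equals total aligned bases of kept reads in span
            assert track.depth.sum() == oracle.sum()


def toy_matrix(counts, lengths):
    df = pd.DataFrame(counts)
    return CountMatrix(
        gene_ids=list(df.index), sample_ids=list(df.columns),
        counts=df, gene_lengths=pd.Series(lengths),
    )


class TestNormalizeExpression:
    def test_hand_computed_fpkm(self):
        cm = toy_matrix(
            {"S1": {"G1": 100, "G2": 10 ** 6 - 100}},
            {"G1": 1000, "G2": 5000},
        )
        table = normalize_expression(cm, ("G1", "G2"))
        assert table.data.at[0, "G1"] == pytest.approx(100.0, abs=1e-9)

    def test_zero_count_gives_zero(self):
        cm = toy_matrix({"S1": {"G1": 0, "G2": 50}}, {"G1": 1000, "G2": 500})
        table = normalize_expression(cm, ("G1", "G2"))
        assert table.data.at[0, "G1"] == 0.0

    def test_scale_invariance_and_linearity(self):
        base = {"S1": {"G1": 100, "G2": 300, "G3": 600}}
        lengths = {"G1": 1000, "G2": 500, "G3": 2000}
        t1 = normalize_expression(toy_matrix(base, lengths), ("G1", "G2"))
        doubled = {"S1": {g: 2 * v for g, v in base["S1"].items()}}
        t2 = normalize_expression(toy_matrix(doubled, lengths), ("G1", "G2"))
        for g in ("G1", "G2"):
            assert t1.data.at[0, g] == pytest.approx(t2.data.at[0, g], rel=1e-12)
        # doubling only G1 (library size ~const) doubles G1's FPKM modulo
        # the library-size change, i.e. FPKM is linear in the count at
        # fixed totals
        cm = toy_matrix(base, lengths)
        totals = cm.counts.sum(axis=0)
        fpkm = cm.counts.at["G1", "S1"] * 1e9 / (1000 * totals["S1"])
        assert t1.data.at[0, "G1"] == pytest.approx(fpkm, rel=1e-12)

    def test_zero_column_total_names_sample(self):
        cm = toy_matrix({"S1": {"G1": 0, "G2": 0}}, {"G1": 1000, "G2": 500})
        with pytest.raises(ValueError, match="S1"):
            normalize_expression(cm, ("G1", "G2"))

    def test_missing_gene(self):
        cm = toy_matrix({"S1": {"G1": 5, "G2": 5}}, {"G1": 10, "G2": 10})
        with pytest.raises(KeyError):
            normalize_expression(cm, ("G1", "G9"))


def bedpe_rec(name):
    return BedpeRecord("1", 0, 1, "1", 10, 11, name)


class TestFlagFusionPositive:
    def make_table(self, samples):
        cm = toy_matrix(
            {s: {"A": 10, "B": 20} for s in samples}, {"A": 100, "B": 100}
        )
        return normalize_expression(cm, ("A", "B"))

    def test_order_sensitive_matching(self):
        table = self.make_table(["S1", "S2", "S3"])
        flagged = flag_fusion_positive(table, {
            "S1": [bedpe_rec("A>>B")],
            "S2": [bedpe_rec("B>>A")],   # reciprocal: must NOT match
            "S3": [],
        })
        got = flagged.data.set_index("sample_id")["fusion_positive"]
        assert got.to_dict() == {"S1": True, "S2": False, "S3": False}

    def test_unknown_sample_warned_and_ignored(self, caplog):
        table = self.make_table(["S1"])
        with caplog.at_level("WARNING"):
            flagged = flag_fusion_positive(table, {"S9": [bedpe_rec("A>>B")]})
        assert not flagged.data["fusion_positive"].any()
        assert "S9" in caplog.text
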