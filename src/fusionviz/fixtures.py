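"""Self-contained toy datasets with known ground truth.

Every external input the tool consumes — genome FASTA (+ .fai), GTF gene
models, a sorted+indexed BAM, BEDPE fusion candidates, domain/ideogram
TSVs and a gene-by-sample count matrix — is generated at toy scale
(kilobase chromosomes, two planted genes) from a seed, together with an
independently computed truth record (expected chimeric cDNA, junction
offset, frame status, peptide, remapped domains, coverage, FPKM).  The
truth is derived from the planted spliced sequences by direct arithmetic
and a codon-table walk, not by calling the annotation pipeline, so it can
serve as the oracle in integration tests.

Two planted genes emulate the classic prostate-cancer geometry when asked
for: a 5' partner contributing a short regulatory head and a 3' partner
contributing most of its coding sequence, optionally both on the reverse
strand of a single chromosome with elevated read depth over the fused 3'
exons.  What the toys deliberately lack: sequencing error, splice-isoform
ambiguity beyond the planted isoforms, and realistic intron/intergenic
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pyfaidx
import pysam

_BASES = "ACGT"
_CODON_ORDER = "TCAG"
_AA64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AA64[16 * i + 4 * j + k]
    for i, a in enumerate(_CODON_ORDER)
    for j, b in enumerate(_CODON_ORDER)
    for k, c in enumerate(_CODON_ORDER)
}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate_walk(seq: str) -> str:
    """Codon-by-codon translation up to (excluding) the first stop."""
    out = []
    for i in range(0, len(seq) - 2, 3):
        aa = CODON_TABLE.get(seq[i : i + 3], "X")
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random stop-free codons + TAA (length 3*n_codons)."""
    body = []
    while len(body) < n_codons - 2:
        codon = _random_seq(rng, 3)
        if CODON_TABLE[codon] != "*":
            body.append(codon)
    return "ATG" + "".join(body) + "TAA"


@dataclass
class PlantedGene:
    """A designed transcript with its own spliced<->genomic arithmetic.

    The mapping here is deliberately independent of the package's
    TranscriptModel so planted truths act as oracles.
    """

    gene_name: str
    tx_id: str
    chrom: str
    strand: str
    spliced: str                       # full spliced sequence, tx order
    exon_spliced_lens: list[int]
    genomic_start: int
    intron_len: int = 150
    cds_spliced: tuple[int, int] | None = None  # half-open on spliced seq

    # computed in __post_init__
    exons_tx: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert sum(self.exon_spliced_lens) == len(self.spliced)
        n = len(self.exon_spliced_lens)
        genomic_order_lens = (
            self.exon_spliced_lens if self.strand == "+"
            else list(reversed(self.exon_spliced_lens))
        )
        placed = []
        g = self.genomic_start
        for ln in genomic_order_lens:
            placed.append((g, g + ln))
            g += ln + self.intron_len
        self.exons_tx = placed if self.strand == "+" else list(reversed(placed))

    @property
    def exons_genomic(self) -> list[tuple[int, int]]:
        return sorted(self.exons_tx)

    @property
    def hull(self) -> tuple[int, int]:
        ex = self.exons_genomic
        return ex[0][0], ex[-1][1]

    def _chunk_offsets(self) -> list[int]:
        offs, acc = [], 0
        for ln in self.exon_spliced_lens:
            offs.append(acc)
            acc += ln
        return offs

    def spliced_to_genomic(self, idx: int) -> int:
        for (s, e), off, ln in zip(
            self.exons_tx, self._chunk_offsets(), self.exon_spliced_lens
        ):
            if off <= idx < off + ln:
                within = idx - off
                return s + within if self.strand == "+" else e - 1 - within
        raise IndexError(idx)

    def paint(self, genome: bytearray) -> None:
        """Write the exon sequences into a chromosome byte buffer."""
        for (s, e), off, ln in zip(
            self.exons_tx, self._chunk_offsets(), self.exon_spliced_lens
        ):
            chunk = self.spliced[off : off + ln]
            if self.strand == "-":
                chunk = revcomp(chunk)
            genome[s:e] = chunk.encode()

    def gtf_lines(self) -> list[str]:
        attrs = (
            f'gene_id "{self.gene_name}"; transcript_id "{self.tx_id}"; '
            f'gene_name "{self.gene_name}";'
        )
        lines = []
        for s, e in self.exons_genomic:
            lines.append(
                f"{self.chrom}\ttoy\texon\t{s + 1}\t{e}\t.\t{self.strand}\t.\t{attrs}"
            )
        if self.cds_spliced is not None:
            cs, ce = self.cds_spliced
            for (s, e), off, ln in zip(
                self.exons_tx, self._chunk_offsets(), self.exon_spliced_lens
            ):
                lo, hi = max(cs, off), min(ce, off + ln)
                if lo >= hi:
                    continue
                if self.strand == "+":
                    gs, ge = s + (lo - off), s + (hi - off)
                else:
                    gs, ge = e - (hi - off), e - (lo - off)
                lines.append(
                    f"{self.chrom}\ttoy\tCDS\t{gs + 1}\t{ge}\t.\t{self.strand}\t0\t{attrs}"
                )
        return lines

    def native_protein(self) -> str:
        assert self.cds_spliced is not None
        return translate_walk(self.spliced[self.cds_spliced[0] :])


@dataclass
class ToyScenario:
    """A generated dataset plus its independently computed ground truth."""

    seed: int
    out_dir: Path
    paths: dict[str, Path]
    gene5: PlantedGene
    gene3: PlantedGene
    gene5_alt: PlantedGene
    gene3_alt: PlantedGene
    s5: int                      # spliced index of last retained 5' base
    s3: int                      # spliced index of first retained 3' base
    bp5: int                     # genomic breakpoint, 5' partner
    bp3: int
    spanning_reads: int
    encompassing_reads: int
    sample_id: str
    n_samples: int
    counts: "object"             # pandas DataFrame genes x samples
    gene_lengths: dict[str, int]
    positive_samples: list[str]
    expected_depth: dict[str, np.ndarray]

    # --- planted truths -------------------------------------------------
    @property
    def expected_cdna(self) -> str:
        return self.gene5.spliced[: self.s5 + 1] + self.gene3.spliced[self.s3 :]

    @property
    def expected_junction_offset(self) -> int:
        return self.s5 + 1

    @property
    def retained5_cds(self) -> int:
        return self.s5 + 1 - self.gene5.cds_spliced[0]

    @property
    def three_cds_offset(self) -> int:
        return self.s3 - self.gene3.cds_spliced[0]

    @property
    def expected_frame(self) -> str:
        return (
            "in_frame"
            if (self.retained5_cds - self.three_cds_offset) % 3 == 0
            else "out_of_frame"
        )

    @property
    def expected_peptide(self) -> str:
        start = self.gene5.cds_spliced[0]
        return translate_walk(self.expected_cdna[start:])

    @property
    def expected_junction_aa(self) -> int:
        return -(-self.retained5_cds // 3)


def _make_genes(
    rng: np.random.Generator, strands: tuple[str, str], in_frame: bool
):
    """Design the two planted genes and the breakpoints."""
    same_chrom = strands == ("-", "-")
    chrom5 = "chr22" if same_chrom else "chr21"
    chrom3 = "chr22" if same_chrom else "chr22"
    start5 = 5200 if same_chrom else 900
    start3 = 600 if same_chrom else 700

    utr5a, cds_a, utr3a = 60, _random_cds(rng, 100), 45
    spliced_a = _random_seq(rng, utr5a) + cds_a + _random_seq(rng, utr3a)
    gene5 = PlantedGene(
        "GENEA", "TXA001", chrom5, strands[0], spliced_a,
        [120, 150, 135], start5, cds_spliced=(utr5a, utr5a + len(cds_a)),
    )
    # second isoform: same exons, shorter CDS confined to exon 2
    gene5_alt = PlantedGene(
        "GENEA", "TXA002", chrom5, strands[0], spliced_a,
        [120, 150, 135], start5, cds_spliced=(150, 249),
    )

    utr5b, cds_b, utr3b = 66, _random_cds(rng, 120), 48
    spliced_b = _random_seq(rng, utr5b) + cds_b + _random_seq(rng, utr3b)
    gene3 = PlantedGene(
        "GENEB", "TXB001", chrom3, strands[1], spliced_b,
        [90, 96, 105, 99, 84], start3, cds_spliced=(utr5b, utr5b + len(cds_b)),
    )
    # short isoform covering only the first two exons: its hull excludes the
    # breakpoint, exercising viability filtering
    gene3_alt = PlantedGene(
        "GENEB", "TXB002", chrom3, strands[1], spliced_b[: 90 + 96],
        [90, 96], start3 if strands[1] == "+" else start3 + 3 * (150) + 105 + 99 + 84,
        cds_spliced=None,
    )

    s5 = 239 if in_frame else 240   # inside exon 2 of the 5' partner
    s3 = 90 + 96 + 105              # first base of exon 4 of the 3' partner
    return gene5, gene5_alt, gene3, gene3_alt, s5, s3


def _write_genome(path: Path, genes, rng: np.random.Generator) -> dict[str, str]:
    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.hull[1] + 400)
    buffers = {
        chrom: bytearray(_random_seq(rng, size).encode())
        for chrom, size in sorted(sizes.items())
    }
    for g in genes:
        g.paint(buffers[g.chrom])
    with open(path, "w") as fh:
        for chrom in sorted(buffers):
            fh.write(f">{chrom}\n")
            seq = buffers[chrom].decode()
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    pyfaidx.Faidx(str(path))  # writes the .fai sidecar
    return {c: b.decode() for c, b in buffers.items()}


def _write_gtf(path: Path, genes) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for line in g.gtf_lines():
                fh.write(line + "\n")


def _bedpe_row(chrom: str, bp: int) -> tuple[str, int, int]:
    # single-base breakpoint encoded as a 1-bp interval (works for both
    # strands under the nearest-junction-end rule)
    return chrom.removeprefix("chr"), bp, bp + 1


def _write_bedpe(path: Path, sc_fields) -> None:
    (chrom5, bp5, strand5, chrom3, bp3, strand3,
     spanning, encompassing, sample) = sc_fields
    c1, s1, e1 = _bedpe_row(chrom5, bp5)
    c2, s2, e2 = _bedpe_row(chrom3, bp3)
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
            "strand1\tstrand2\tspanning\tencompassing\tsample\n"
        )
        fh.write(
            f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\tGENEA>>GENEB\t.\t"
            f"{strand5}\t{strand3}\t{spanning}\t{encompassing}\t{sample}\n"
        )


def _write_cohort_bedpe(path: Path, sc_fields, positive, negative_decoy) -> None:
    (chrom5, bp5, strand5, chrom3, bp3, strand3, spanning, _, _) = sc_fields
    c1, s1, e1 = _bedpe_row(chrom5, bp5)
    c2, s2, e2 = _bedpe_row(chrom3, bp3)
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
            "strand1\tstrand2\tspanning\tencompassing\tsample\n"
        )
        for s in positive:
            fh.write(
                f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\tGENEA>>GENEB\t.\t"
                f"{strand5}\t{strand3}\t{spanning}\t0\t{s}\n"
            )
        # reciprocal-order fusion in one negative sample: must NOT flag it
        fh.write(
            f"{c2}\t{s2}\t{e2}\t{c1}\t{s1}\t{e1}\tGENEB>>GENEA\t.\t"
            f"{strand3}\t{strand5}\t2\t0\t{negative_decoy}\n"
        )


def _write_domains(path: Path) -> None:
    rows = [
        ("TXA001", "HELX", 5, 30),
        ("TXA001", "SER-PROT", 40, 90),
        ("TXB001", "PNT", 20, 50),
        ("TXB001", "ETS", 85, 115),
        ("TXZ999", "ORPHAN", 1, 10),
    ]
    with open(path, "w") as fh:
        fh.write("#id\tdomain\tstart_aa\tend_aa\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def _write_ideogram(path: Path, chrom_sizes: dict[str, int]) -> None:
    stains = ["gneg", "gpos50", "gneg", "gpos25"]
    with open(path, "w") as fh:
        for chrom, size in sorted(chrom_sizes.items()):
            edges = np.linspace(0, size, 5, dtype=int)
            for i in range(4):
                arm = "p" if i < 2 else "q"
                fh.write(
                    f"{chrom}\t{edges[i]}\t{edges[i + 1]}\t{arm}1{i + 1}\t{stains[i]}\n"
                )


def _make_reads(genome: dict[str, str], gene: PlantedGene, depth_per_exon,
                name_prefix: str):
    """Deterministic exon-tiling reads; returns (records, depth_delta).

    Each record: (qname, chrom, pos, cigar, seq, flag).  Includes spliced
    (N-gapped), soft-clipped, duplicate and secondary reads so that filter
    and CIGAR-walking code paths are exercised.
    """
    reads = []
    rlen = 40
    exons = gene.exons_genomic
    for ei, ((s, e), depth) in enumerate(zip(exons, depth_per_exon)):
        span = max(e - s - rlen, 1)
        for k in range(depth):
            pos = s + (k * span) // max(depth - 1, 1) if depth > 1 else s
            pos = min(pos, e - rlen) if e - s >= rlen else s
            ln = min(rlen, e - pos)
            seq = genome[gene.chrom][pos : pos + ln]
            reads.append((f"{name_prefix}_e{ei}_{k}", gene.chrom, pos,
                          f"{ln}M", seq, 0))
    # two spliced reads across each intron in genomic order
    for ei in range(len(exons) - 1):
        (s1, e1), (s2, e2) = exons[ei], exons[ei + 1]
        gap = s2 - e1
        for k in range(2):
            a = b = 20
            pos = e1 - a
            seq = genome[gene.chrom][pos:e1] + genome[gene.chrom][s2 : s2 + b]
            reads.append((f"{name_prefix}_sj{ei}_{k}", gene.chrom, pos,
                          f"{a}M{gap}N{b}M", seq, 0))
    # one soft-clipped read at the first exon
    s0, e0 = exons[0]
    m = min(30, e0 - s0)
    reads.append((f"{name_prefix}_clip", gene.chrom, s0,
                  f"6S{m}M", "A" * 6 + genome[gene.chrom][s0 : s0 + m], 0))
    # excluded reads: duplicate + secondary copies of the first read
    q0, c0, p0, cg0, sq0, _ = reads[0]
    reads.append((q0 + "_dup", c0, p0, cg0, sq0, 0x400))
    reads.append((q0 + "_sec", c0, p0, cg0, sq0, 0x100))
    return reads


def _cigar_blocks(pos: int, cigar: str):
    """Reference blocks covered by M/=/X ops (used for the depth truth)."""
    import re

    blocks, ref = [], pos
    for ln, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        ln = int(ln)
        if op in "M=X":
            blocks.append((ref, ref + ln))
            ref += ln
        elif op in "DN":
            ref += ln
    return blocks


def _write_bam(path: Path, genome: dict[str, str], read_sets) -> dict[str, np.ndarray]:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": chrom, "LN": len(seq)} for chrom, seq in sorted(genome.items())
        ],
    }
    tids = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
    depth = {c: np.zeros(len(s), dtype=np.int64) for c, s in genome.items()}
    unsorted = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
        for qname, chrom, pos, cigar, seq, flag in read_sets:
            a = pysam.AlignedSegment()
            a.query_name = qname
            a.query_sequence = seq
            a.flag = flag
            a.reference_id = tids[chrom]
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            bam.write(a)
            if not flag & (0x400 | 0x100 | 0x800 | 0x4):
                for bs, be in _cigar_blocks(pos, cigar):
                    depth[chrom][bs:be] += 1
    # --no-PG keeps the header free of run-specific paths (determinism)
    pysam.sort("--no-PG", "-o", str(path), str(unsorted))
    unsorted.unlink()
    pysam.index(str(path))
    return depth


def make_scenario(
    seed: int,
    out_dir: str | Path,
    n_samples: int = 12,
    in_frame: bool = True,
    strands: tuple[str, str] = ("-", "-"),
    base_depth: int = 8,
    fusion_boost: int = 4,
    spanning_reads: int = 7,
    encompassing_reads: int = 12,
) -> ToyScenario:
    """Generate a complete toy dataset on disk, deterministic per seed.

    Defaults emulate the classic reverse-strand single-chromosome deletion
    geometry: both partners on '-', the 3' partner's fused exons covered at
    ``fusion_boost``-fold elevated depth, and a 12-sample cohort in which
    fusion-positive samples over-express the 3' gene.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    gene5, gene5_alt, gene3, gene3_alt, s5, s3 = _make_genes(rng, strands, in_frame)
    genes = [gene5, gene5_alt, gene3, gene3_alt]
    paths = {
        "fasta": out_dir / "genome.fa",
        "gtf": out_dir / "annotation.gtf",
        "bam": out_dir / "sample.bam",
        "bedpe": out_dir / "fusions.bedpe",
        "cohort_bedpe": out_dir / "cohort.bedpe",
        "domains": out_dir / "domains.tsv",
        "ideogram": out_dir / "ideogram.tsv",
        "counts": out_dir / "counts.tsv",
    }
    genome = _write_genome(paths["fasta"], genes, rng)
    _write_gtf(paths["gtf"], genes)

    bp5 = gene5.spliced_to_genomic(s5)
    bp3 = gene3.spliced_to_genomic(s3)
    sample_id = "S01"
    sc_fields = (
        gene5.chrom, bp5, gene5.strand, gene3.chrom, bp3, gene3.strand,
        spanning_reads, encompassing_reads, sample_id,
    )
    _write_bedpe(paths["bedpe"], sc_fields)

    n_pos = max(n_samples // 3, 1)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    positive = samples[:n_pos]
    _write_cohort_bedpe(paths["cohort_bedpe"], sc_fields, positive,
                        negative_decoy=samples[-1])
    _write_domains(paths["domains"])
    _write_ideogram(paths["ideogram"], {c: len(s) for c, s in genome.items()})

    # BAM: 5' partner at base depth everywhere; 3' partner elevated over the
    # exons retained in the fusion (exon 4 onward, transcription order)
    depth5 = [base_depth] * len(gene5.exon_spliced_lens)
    fused_from = 3  # 0-based tx-order index of the first fused 3' exon
    depth3_tx = [
        base_depth * fusion_boost if i >= fused_from else base_depth
        for i in range(len(gene3.exon_spliced_lens))
    ]
    # _make_reads wants depths in genomic order
    order3 = (
        depth3_tx if gene3.strand == "+" else list(reversed(depth3_tx))
    )
    reads = _make_reads(genome, gene5, depth5, "rA") + _make_reads(
        genome, gene3, order3, "rB"
    )
    expected_depth = _write_bam(paths["bam"], genome, reads)

    # cohort counts: GENEB elevated in fusion-positive samples
    import pandas as pd

    gene_lengths = {
        "GENEA": len(gene5.spliced),
        "GENEB": len(gene3.spliced),
        "DECOY1": 800,
        "DECOY2": 650,
        "DECOY3": 900,
    }
    base = rng.integers(50, 500, size=(len(gene_lengths), n_samples))
    counts = pd.DataFrame(base, index=list(gene_lengths), columns=samples)
    for s in positive:
        counts.loc["GENEB", s] = int(counts.loc["GENEB", s]) * 5
    with open(paths["counts"], "w") as fh:
        fh.write("Geneid\tLength\t" + "\t".join(samples) + "\n")
        for g in counts.index:
            fh.write(
                f"{g}\t{gene_lengths[g]}\t"
                + "\t".join(str(int(v)) for v in counts.loc[g])
                + "\n"
            )

    return ToyScenario(
        seed=seed, out_dir=out_dir, paths=paths,
        gene5=gene5, gene3=gene3, gene5_alt=gene5_alt, gene3_alt=gene3_alt,
        s5=s5, s3=s3, bp5=bp5, bp3=bp3,
        spanning_reads=spanning_reads, encompassing_reads=encompassing_reads,
        sample_id=sample_id, n_samples=n_samples, counts=counts,
        gene_lengths=gene_lengths, positive_samples=positive,
        expected_depth=expected_depth,
    )


def truth_report(s: ToyScenario) -> dict:
    """The planted ground truth, computed by independent arithmetic."""
    import pandas as pd

    counts: pd.DataFrame = s.counts
    totals = counts.sum(axis=0)
    fpkm = {
        g: {
            smp: counts.at[g, smp] * 1e9 / (s.gene_lengths[g] * totals[smp])
            for smp in counts.columns
        }
        for g in ("GENEA", "GENEB")
    }
    exon_means = {}
    for gene in (s.gene5, s.gene3):
        dep = s.expected_depth[gene.chrom]
        # transcription order, matching exon numbering in the plots
        exon_means[gene.gene_name] = [
            float(dep[a:b].mean()) for a, b in gene.exons_tx
        ]
    dom = _expected_domains(s)
    return {
        "cdna": s.expected_cdna,
        "junction_offset": s.expected_junction_offset,
        "frame": s.expected_frame,
        "peptide": s.expected_peptide,
        "junction_aa": s.expected_junction_aa,
        "domains": dom,
        "exon_mean_depth": exon_means,
        "fpkm": fpkm,
        "positive_samples": list(s.positive_samples),
    }


def _expected_domains(s: ToyScenario) -> list[tuple[str, int, int, float]]:
    """Remapped-domain truth by direct clipping/shift arithmetic."""
    pep_len = len(s.expected_peptide)
    j = s.expected_junction_aa
    out = []
    for name, a, b in (("HELX", 5, 30), ("SER-PROT", 40, 90)):
        end = min(b, j, pep_len)
        if a <= end:
            out.append((name, a, end, (end - a + 1) / (b - a + 1)))
    if s.expected_frame == "in_frame":
        shift = (s.retained5_cds - s.three_cds_offset) // 3
        for name, a, b in (("PNT", 20, 50), ("ETS", 85, 115)):
            start = max(a + shift, j + 1)
            end = min(b + shift, pep_len)
            if start <= end:
                out.append((name, start, end, (end - start + 1) / (b - a + 1)))
    return sorted(out, key=lambda d: (d[1], d[2], d[0]))


# ---------------------------------------------------------------------------
# Lightweight in-memory toys for property tests: no files, just sequences,
# planted layouts and an expected cDNA built by a per-base genome walk.
# ---------------------------------------------------------------------------

@dataclass
class InMemoryToy:
    genome: dict[str, str]
    gene5: PlantedGene
    gene3: PlantedGene
    s5: int
    s3: int
    bp5: int
    bp3: int

    @property
    def expected_cdna(self) -> str:
        """Per-base genome walk over the retained spliced positions."""
        out = []
        for idx in range(self.s5 + 1):
            g = self.gene5.spliced_to_genomic(idx)
            base = self.genome[self.gene5.chrom][g]
            out.append(base if self.gene5.strand == "+" else base.translate(_COMP))
        for idx in range(self.s3, len(self.gene3.spliced)):
            g = self.gene3.spliced_to_genomic(idx)
            base = self.genome[self.gene3.chrom][g]
            out.append(base if self.gene3.strand == "+" else base.translate(_COMP))
        return "".join(out)


def random_toy_fusion(
    rng: np.random.Generator,
    strands: tuple[str, str] | None = None,
    force_frame: str | None = None,
) -> InMemoryToy:
    """A random two-gene fusion toy with planted coding structure.

    Breakpoints are exonic and inside the CDS of both partners; when
    ``force_frame`` is ``"in_frame"``/``"out_of_frame"`` the 3' entry
    offset is adjusted so the planted phase matches.
    """
    if strands is None:
        strands = (
            "+-"[rng.integers(0, 2)],
            "+-"[rng.integers(0, 2)],
        )

    def build(name, tx, chrom, strand, start):
        utr5 = int(rng.integers(12, 60))
        n_codons = int(rng.integers(40, 120))
        utr3 = int(rng.integers(12, 50))
        cds = _random_cds(rng, n_codons)
        spliced = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)
        n_ex = int(rng.integers(2, 6))
        cuts = sorted(rng.choice(np.arange(1, len(spliced)), size=n_ex - 1,
                                 replace=False).tolist())
        lens = np.diff([0, *cuts, len(spliced)]).tolist()
        return PlantedGene(
            name, tx, chrom, strand, spliced, lens, start,
            intron_len=int(rng.integers(60, 200)),
            cds_spliced=(utr5, utr5 + len(cds)),
        )

    g5 = build("TOY5", "TX5", "chr1", strands[0], int(rng.integers(100, 400)))
    g3 = build("TOY3", "TX3", "chr2", strands[1], int(rng.integers(100, 400)))

    cs5, ce5 = g5.cds_spliced
    s5 = int(rng.integers(cs5 + 5, ce5 - 4))
    cs3, ce3 = g3.cds_spliced
    if force_frame == "in_frame":
        # codon-aligned junction: the fusion peptide is then exactly the
        # 5' native prefix followed by the 3' native suffix
        s5 -= (s5 + 1 - cs5) % 3
    r5 = s5 + 1 - cs5
    if force_frame is None:
        s3 = int(rng.integers(cs3, ce3 - 3))
    else:
        want = 0 if force_frame == "in_frame" else int(rng.integers(1, 3))
        candidates = [
            o for o in range(0, ce3 - cs3 - 3) if (r5 - o) % 3 == want
        ]
        s3 = cs3 + int(rng.choice(candidates))

    genome = {}
    for g in (g5, g3):
        size = g.hull[1] + 200
        buf = bytearray(_random_seq(rng, size).encode())
        g.paint(buf)
        genome[g.chrom] = buf.decode()
    return InMemoryToy(
        genome=genome, gene5=g5, gene3=g3, s5=s5, s3=s3,
        bp5=g5.spliced_to_genomic(s5), bp3=g3.spliced_to_genomic(s3),
    )


def toy_models(toy: InMemoryToy):
    """Package-side TranscriptModels for an in-memory toy (for pipelines)."""
    from .gene_models import TranscriptModel

    def to_model(g: PlantedGene) -> TranscriptModel:
        cds_span = None
        if g.cds_spliced is not None:
            cs, ce = g.cds_spliced
            a = g.spliced_to_genomic(cs)
            b = g.spliced_to_genomic(ce - 1)
            cds_span = (min(a, b), max(a, b) + 1)
        return TranscriptModel(
            transcript_id=g.tx_id, gene_id=g.gene_name, gene_name=g.gene_name,
            chrom=g.chrom.removeprefix("chr"), strand=g.strand,
            exons=g.exons_genomic, cds_span=cds_span,
        )

    return to_model(toy.gene5), to_model(toy.gene3)
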