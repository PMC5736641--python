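"""Coverage tracks and cohort-level partner-gene expression.

Per-base read depth over each partner gene's transcript hull is computed
from a coordinate-sorted indexed BAM, counting aligned (M/=/X) bases of
primary, non-duplicate alignments only — deletions, introns (N) and clips
contribute nothing.  Cohort expression is FPKM computed from a
FeatureCounts-style gene-by-sample count matrix; samples are flagged
fusion-positive when their fusion-candidate list contains the (ordered)
``GENE5>>GENE3`` pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .gene_models import TranscriptModel
from .io_formats import BedpeRecord, CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageTrack",
    "CohortExpressionTable",
    "compute_coverage",
    "normalize_expression",
    "flag_fusion_positive",
]


@dataclass
class CoverageTrack:
    """Per-base depth over one partner gene's transcript hull."""

    gene: str
    chrom: str
    span: tuple[int, int]  # 0-based half-open genomic interval
    depth: np.ndarray      # len == span length, >= 0
    exon_boundaries: list[int]
    junction_pos: int

    def __post_init__(self) -> None:
        lo, hi = self.span
        assert len(self.depth) == hi - lo


@dataclass
class CohortExpressionTable:
    """Normalized expression of both partners per sample, with fusion flags.

    ``data`` columns: ``sample_id``, one expression column per partner gene,
    ``fusion_positive``.
    """

    gene5: str
    gene3: str
    data: pd.DataFrame
    unit: str = "FPKM"


def _keep_read(read: pysam.AlignedSegment, mapq: int) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and not read.is_duplicate
        and read.mapping_quality >= mapq
    )


def _bam_reference(bam: pysam.AlignmentFile, chrom: str) -> str:
    for cand in (chrom, f"chr{chrom}", chrom.removeprefix("chr")):
        if cand in bam.references:
            return cand
    raise ValueError(f"chromosome {chrom!r} absent from BAM header")


def compute_coverage(
    bam_path: str,
    transcript: TranscriptModel,
    junction: int,
    mapq: int = 0,
) -> CoverageTrack:
    """Per-base aligned-read depth over a transcript's genomic hull.

    ``depth[i]`` counts read bases aligned (CIGAR M/=/X) to
    ``span.start + i``; duplicate, secondary and supplementary alignments
    are excluded, as are reads below the MAPQ threshold.
    """
    lo, hi = transcript.hull
    depth = np.zeros(hi - lo, dtype=np.int64)
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        ref = _bam_reference(bam, transcript.chrom)
        for read in bam.fetch(ref, lo, hi):
            if not _keep_read(read, mapq):
                continue
            for bs, be in read.get_blocks():  # M/=/X blocks; N/D/S skipped
                s, e = max(bs, lo), min(be, hi)
                if s < e:
                    depth[s - lo : e - lo] += 1
    boundaries = sorted({b for s, e in transcript.exons for b in (s, e)})
    return CoverageTrack(
        gene=transcript.gene_name,
        chrom=transcript.chrom,
        span=(lo, hi),
        depth=depth,
        exon_boundaries=boundaries,
        junction_pos=junction,
    )


def normalize_expression(
    cm: CountMatrix, genes: tuple[str, str], unit: str = "FPKM"
) -> CohortExpressionTable:
    """FPKM for the two partner genes across every sample.

    FPKM = count * 1e9 / (gene_length_bp * total mapped counts in the
    sample's column); the column total runs over all genes in the matrix.
    Fusion flags start out False; see :func:`flag_fusion_positive`.
    """
    gene5, gene3 = genes
    for g in genes:
        if g not in cm.counts.index:
            raise KeyError(f"gene {g!r} absent from count matrix")
    totals = cm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total mapped counts for sample(s) {list(zero.index)}")
    rows = []
    for sample in cm.sample_ids:
        rec = {"sample_id": sample}
        for g in genes:
            rec[g] = float(
                cm.counts.at[g, sample] * 1e9 / (cm.gene_lengths.at[g] * totals[sample])
            )
        rec["fusion_positive"] = False
        rows.append(rec)
    return CohortExpressionTable(
        gene5=gene5, gene3=gene3, data=pd.DataFrame(rows), unit=unit
    )


def flag_fusion_positive(
    table: CohortExpressionTable,
    cohort_bedpe: dict[str, list[BedpeRecord]],
    genes: tuple[str, str] | None = None,
) -> CohortExpressionTable:
    """Mark samples whose candidate list contains the ordered gene pair.

    The match is on the BEDPE ``name`` field against ``GENE5>>GENE3``
    exactly — the reciprocal ``GENE3>>GENE5`` fusion is a different event
    and does not count.  Samples present in the BEDPE map but absent from
    the table are ignored with a warning.
    """
    gene5, gene3 = genes if genes is not None else (table.gene5, table.gene3)
    wanted = f"{gene5}>>{gene3}"
    known = set(table.data["sample_id"])
    flags = dict.fromkeys(known, False)
    for sample, records in cohort_bedpe.items():
        if sample not in known:
            logger.warning("sample %r in fusion list but not in count matrix", sample)
            continue
        flags[sample] = any(rec.name == wanted for rec in records)
    out = table.data.copy()
    out["fusion_positive"] = out["sample_id"].map(flags)
    return CohortExpressionTable(
        gene5=table.gene5, gene3=table.gene3, data=out, unit=table.unit
    )
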