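"""Fusion transcript assembly.

Maps each genomic breakpoint onto the selected isoform of its partner gene,
collects the retained exon segments (5' partner: transcription start up to
and including the breakpoint base; 3' partner: breakpoint base to
transcription end), splices them into the chimeric cDNA (reverse-
complementing '-'-strand partners), and provides the supporting-read glyph
binning used by the structure plot.

Intronic breakpoints — common when the underlying event is a DNA-level
rearrangement — are snapped to the nearest retained-side exon boundary and
flagged, rather than rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

from Bio.Seq import Seq

from .gene_models import GeneModelStore, TranscriptModel, select_isoform
from .io_formats import BedpeRecord, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "FusionCandidate",
    "RetainedSegment",
    "FusionTranscript",
    "candidate_from_bedpe",
    "breakpoint_from_interval",
    "retained_segments",
    "build_fusion_transcript",
    "glyph_count",
    "enumerate_isoform_pairs",
]

Role = Literal["five_prime", "three_prime"]


@dataclass
class FusionCandidate:
    """One fusion event: 5' and 3' breakpoints with supporting-read counts."""

    five_chrom: str
    five_pos: int
    five_strand: str
    five_gene: str
    three_chrom: str
    three_pos: int
    three_strand: str
    three_gene: str
    spanning_reads: int = 0
    encompassing_reads: int = 0
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not self.five_gene or not self.three_gene:
            raise ValueError("fusion partner gene symbols must be non-empty")
        if self.spanning_reads < 0 or self.encompassing_reads < 0:
            raise ValueError("supporting-read counts must be >= 0")

    @property
    def name(self) -> str:
        return f"{self.five_gene}>>{self.three_gene}"


@dataclass
class RetainedSegment:
    """One exonic genomic interval retained in the fusion transcript."""

    source: Role
    exon_ordinal: int  # 1-based, transcription order on the native transcript
    genomic_interval: tuple[int, int]
    truncated: bool = False

    @property
    def length(self) -> int:
        s, e = self.genomic_interval
        return e - s


@dataclass
class FusionTranscript:
    """The assembled chimeric transcript.

    ``segments`` lists all 5'-partner segments in transcription order
    followed by all 3'-partner segments; ``junction_offset`` is the cDNA
    index of the first 3'-partner base (== total 5' retained length).
    """

    five_model: TranscriptModel
    three_model: TranscriptModel
    segments: list[RetainedSegment]
    cdna: str
    junction_offset: int
    candidate: FusionCandidate
    snapped: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def five_segments(self) -> list[RetainedSegment]:
        return [s for s in self.segments if s.source == "five_prime"]

    @property
    def three_segments(self) -> list[RetainedSegment]:
        return [s for s in self.segments if s.source == "three_prime"]


def breakpoint_from_interval(start: int, end: int, strand: str, role: Role) -> int:
    """Single breakpoint base from a BEDPE interval.

    Fusion callers in the paired-interval dialect encode single-base
    breakpoints as 1-bp intervals; wider intervals degrade gracefully by
    taking the interval end nearest the junction on the transcription
    strand.  For the 5' partner the junction is at the partner's 3' side
    (``end-1`` on '+', ``start`` on '-'); for the 3' partner it is at the
    partner's 5' side (the mirror rule).
    """
    if role == "five_prime":
        return end - 1 if strand == "+" else start
    return start if strand == "+" else end - 1


def candidate_from_bedpe(
    rec: BedpeRecord, store: GeneModelStore | None = None
) -> FusionCandidate:
    """Turn a parsed BEDPE row into a :class:`FusionCandidate`.

    Strands given as ``.`` are taken from the GTF model of the partner gene
    when a store is supplied; an explicit strand that contradicts the model
    is an error (checked later at build time).
    """
    strand1, strand2 = rec.strand1, rec.strand2
    if store is not None:
        if strand1 == "." and rec.gene5 in store.genes():
            strand1 = store.transcripts_of(rec.gene5)[0].strand
        if strand2 == "." and rec.gene3 in store.genes():
            strand2 = store.transcripts_of(rec.gene3)[0].strand
    return FusionCandidate(
        five_chrom=normalize_chrom(rec.chrom1),
        five_pos=breakpoint_from_interval(rec.start1, rec.end1, strand1, "five_prime"),
        five_strand=strand1,
        five_gene=rec.gene5,
        three_chrom=normalize_chrom(rec.chrom2),
        three_pos=breakpoint_from_interval(rec.start2, rec.end2, strand2, "three_prime"),
        three_strand=strand2,
        three_gene=rec.gene3,
        spanning_reads=rec.spanning_reads,
        encompassing_reads=rec.encompassing_reads,
        sample_id=rec.sample_id,
    )


def _snap_intronic(
    transcript: TranscriptModel, breakpoint: int, role: Role
) -> int:
    """Snap an intronic breakpoint to the nearest retained-side exon base.

    5' role: last base (transcription order) of the last fully upstream
    exon; 3' role: first base of the next downstream exon.
    """
    tx_exons = transcript.exons_transcription_order()
    plus = transcript.strand == "+"
    if role == "five_prime":
        upstream = [
            (s, e) for s, e in tx_exons
            if (e <= breakpoint if plus else s > breakpoint)
        ]
        if not upstream:
            raise ValueError(
                f"intronic breakpoint {breakpoint} precedes all exons of "
                f"{transcript.transcript_id} for the 5' role"
            )
        s, e = upstream[-1]
        return e - 1 if plus else s
    downstream = [
        (s, e) for s, e in tx_exons
        if (s > breakpoint if plus else e <= breakpoint)
    ]
    if not downstream:
        raise ValueError(
            f"intronic breakpoint {breakpoint} follows all exons of "
            f"{transcript.transcript_id} for the 3' role"
        )
    s, e = downstream[0]
    return s if plus else e - 1


def retained_segments(
    transcript: TranscriptModel, breakpoint: int, role: Role
) -> tuple[list[RetainedSegment], bool]:
    """Exonic intervals retained by one partner, in transcription order.

    Returns ``(segments, snapped)`` where ``snapped`` reports that an
    intronic breakpoint was moved to the retained-side exon boundary (in
    which case no segment is marked truncated).  The breakpoint base itself
    is always retained.
    """
    lo, hi = transcript.hull
    if not lo <= breakpoint < hi:
        raise ValueError(
            f"breakpoint {breakpoint} outside hull [{lo},{hi}) of "
            f"{transcript.transcript_id}"
        )
    tx_exons = transcript.exons_transcription_order()
    snapped = False
    if not any(s <= breakpoint < e for s, e in tx_exons):
        breakpoint = _snap_intronic(transcript, breakpoint, role)
        snapped = True
        logger.warning(
            "intronic breakpoint snapped to %d on %s (%s role)",
            breakpoint, transcript.transcript_id, role,
        )

    plus = transcript.strand == "+"
    segments: list[RetainedSegment] = []
    for ordinal, (s, e) in enumerate(tx_exons, start=1):
        if role == "five_prime":
            if plus:
                kept = (s, min(e, breakpoint + 1)) if s <= breakpoint else None
            else:
                kept = (max(s, breakpoint), e) if e > breakpoint else None
        else:
            if plus:
                kept = (max(s, breakpoint), e) if e > breakpoint else None
            else:
                kept = (s, min(e, breakpoint + 1)) if s <= breakpoint else None
        if kept is None or kept[0] >= kept[1]:
            continue
        segments.append(
            RetainedSegment(
                source=role,
                exon_ordinal=ordinal,
                genomic_interval=kept,
                truncated=kept != (s, e),
            )
        )
    if not segments:
        raise ValueError(
            f"no exonic sequence retained for {role} on {transcript.transcript_id}"
        )
    return segments, snapped


def _segment_seq(genome, chrom: str, seg: RetainedSegment, strand: str) -> str:
    s, e = seg.genomic_interval
    raw = str(genome[chrom][s:e]).upper()
    return raw if strand == "+" else str(Seq(raw).reverse_complement())


def _lookup_chrom(genome, chrom: str) -> str:
    """Resolve a normalized chromosome name against the FASTA's keys."""
    for cand in (chrom, f"chr{chrom}"):
        try:
            genome[cand]
            return cand
        except KeyError:
            continue
    raise KeyError(f"chromosome {chrom!r} absent from genome")


def build_fusion_transcript(
    candidate: FusionCandidate,
    five_model: TranscriptModel,
    three_model: TranscriptModel,
    genome,
) -> FusionTranscript:
    """Assemble the chimeric cDNA for one isoform pair.

    ``genome`` is any faidx-style accessor supporting
    ``genome[chrom][start:end]`` (e.g. ``pyfaidx.Fasta``); '-'-strand
    partners are read in transcription order via reverse complement.
    """
    for strand, model, side in (
        (candidate.five_strand, five_model, "5'"),
        (candidate.three_strand, three_model, "3'"),
    ):
        if strand not in {".", model.strand}:
            raise ValueError(
                f"{side} partner strand {strand!r} contradicts GTF model "
                f"{model.transcript_id} ({model.strand})"
            )

    segs5, snap5 = retained_segments(five_model, candidate.five_pos, "five_prime")
    segs3, snap3 = retained_segments(three_model, candidate.three_pos, "three_prime")
    chrom5 = _lookup_chrom(genome, five_model.chrom)
    chrom3 = _lookup_chrom(genome, three_model.chrom)
    part5 = "".join(_segment_seq(genome, chrom5, s, five_model.strand) for s in segs5)
    part3 = "".join(_segment_seq(genome, chrom3, s, three_model.strand) for s in segs3)
    warnings = []
    if snap5 or snap3:
        warnings.append("junction snapped from intronic breakpoint")
    return FusionTranscript(
        five_model=five_model,
        three_model=three_model,
        segments=segs5 + segs3,
        cdna=part5 + part3,
        junction_offset=len(part5),
        candidate=candidate,
        snapped=snap5 or snap3,
        warnings=warnings,
    )


def glyph_count(n_supporting_reads: int) -> int:
    """Number of read glyphs drawn for a supporting-read count.

    The structure plot conserves space by showing 1, 2 or 3 glyphs for 1,
    2-10 or >10 supporting reads respectively; zero reads draw no glyph.
    """
    if n_supporting_reads < 0:
        raise ValueError("supporting-read count must be >= 0")
    if n_supporting_reads == 0:
        return 0
    if n_supporting_reads == 1:
        return 1
    if n_supporting_reads <= 10:
        return 2
    return 3


def enumerate_isoform_pairs(
    candidate: FusionCandidate, store: GeneModelStore
) -> list[tuple[TranscriptModel, TranscriptModel]]:
    """All viable (5' isoform, 3' isoform) pairs for a fusion candidate.

    A pair is viable when both breakpoints fall within the respective
    transcript hulls.  The default pair from :func:`select_isoform` is
    listed first; the remainder follow in accession order.
    """
    reasons: list[str] = []

    def viable(model: TranscriptModel, pos: int) -> bool:
        lo, hi = model.hull
        ok = lo <= pos < hi
        if not ok:
            reasons.append(
                f"{model.transcript_id}: breakpoint {pos} outside hull [{lo},{hi})"
            )
        return ok

    fives = [
        t for t in store.transcripts_of(candidate.five_gene)
        if viable(t, candidate.five_pos)
    ]
    threes = [
        t for t in store.transcripts_of(candidate.three_gene)
        if viable(t, candidate.three_pos)
    ]
    pairs = [(f, t) for f in fives for t in threes]
    if not pairs:
        raise ValueError(
            f"no viable isoform pair for {candidate.name}: " + "; ".join(reasons)
        )
    default = (
        select_isoform(store, candidate.five_gene),
        select_isoform(store, candidate.three_gene),
    )
    if default in pairs:
        pairs.remove(default)
        pairs.insert(0, default)
    return pairs
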