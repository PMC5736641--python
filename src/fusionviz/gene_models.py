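"""Transcript-model store built from GTF, plus isoform selection.

GTF coordinates (1-based inclusive) are converted to 0-based half-open at
load time.  The store indexes every transcript by gene id and gene symbol
and keeps a per-chromosome interval index so that a genomic breakpoint can
be mapped to candidate transcripts.

The isoform used to reconstruct a fusion defaults to a deterministic
"representative" transcript of each partner: an annotated canonical tag if
the GTF carries one, otherwise the longest CDS, otherwise the longest
spliced transcript, with a lexicographic accession tie-break.  Users can
override the choice with an explicit accession.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
from intervaltree import IntervalTree

from .io_formats import FormatError, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "GeneModelStore",
    "parse_gtf",
    "select_isoform",
    "exon_ordinal",
    "INTRONIC",
]

#: Sentinel returned by :func:`exon_ordinal` for intronic positions.
INTRONIC = "intronic"


@dataclass
class TranscriptModel:
    """One isoform: ordered exons and an optional CDS span on a chromosome.

    ``exons`` are 0-based half-open genomic intervals sorted by genomic
    start; ``cds_span`` is the genomic hull of the CDS features (absent for
    non-coding transcripts).  ``canonical`` records whether the GTF tagged
    this isoform as the gene's canonical one.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: tuple[int, int] | None = None
    canonical: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise FormatError(
                    f"{self.transcript_id}: overlapping exons [{s1},{e1}) / [{s2},..)"
                )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.transcript_id}: strand must be + or -")

    @property
    def hull(self) -> tuple[int, int]:
        """Genomic span from first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        """Spliced (exon-intersected) length of the CDS span, 0 if non-coding."""
        if self.cds_span is None:
            return 0
        cs, ce = self.cds_span
        return sum(max(0, min(e, ce) - max(s, cs)) for s, e in self.exons)

    def exons_transcription_order(self) -> list[tuple[int, int]]:
        """Exons ordered 5'->3' along the transcript (reversed for '-')."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def genomic_to_spliced(self, pos: int) -> int:
        """Spliced (transcript) offset of an exonic genomic base.

        Raises ``ValueError`` for intronic or out-of-hull positions.
        """
        offset = 0
        for s, e in self.exons_transcription_order():
            if s <= pos < e:
                return offset + (pos - s if self.strand == "+" else e - 1 - pos)
            offset += e - s
        raise ValueError(
            f"position {pos} not exonic in {self.transcript_id}"
        )

    def spliced_to_genomic(self, offset: int) -> int:
        """Genomic position of a spliced transcript offset (inverse map)."""
        acc = 0
        for s, e in self.exons_transcription_order():
            if acc <= offset < acc + (e - s):
                within = offset - acc
                return s + within if self.strand == "+" else e - 1 - within
            acc += e - s
        raise ValueError(f"spliced offset {offset} beyond {self.transcript_id}")


@dataclass
class GeneModelStore:
    """Indexed collection of transcript models.

    Every transcript is retrievable both by ``gene_id`` and ``gene_name``;
    a per-chromosome interval tree maps genomic positions to the
    transcripts whose hull contains them.
    """

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    _by_gene: dict[str, list[str]] = field(default_factory=dict)
    _trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, tm: TranscriptModel) -> None:
        self.transcripts[tm.transcript_id] = tm
        for key in {tm.gene_id, tm.gene_name}:
            self._by_gene.setdefault(key, []).append(tm.transcript_id)
        lo, hi = tm.hull
        self._trees.setdefault(tm.chrom, IntervalTree()).addi(
            lo, hi, tm.transcript_id
        )

    def genes(self) -> set[str]:
        return set(self._by_gene)

    def transcripts_of(self, gene: str) -> list[TranscriptModel]:
        """All isoforms of a gene (by symbol or id), sorted by accession."""
        if gene not in self._by_gene:
            raise KeyError(f"gene {gene!r} not in GTF store")
        return sorted(
            (self.transcripts[t] for t in self._by_gene[gene]),
            key=lambda t: t.transcript_id,
        )

    def transcripts_at(self, chrom: str, pos: int) -> list[TranscriptModel]:
        """Transcripts whose hull covers a genomic position."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted(
            (self.transcripts[iv.data] for iv in tree[pos]),
            key=lambda t: t.transcript_id,
        )


def _attr(feature: gffutils.Feature, key: str) -> str | None:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def parse_gtf(path: str) -> GeneModelStore:
    """Build a :class:`GeneModelStore` from a GTF file.

    Exon coordinates are converted to 0-based half-open; the CDS span per
    transcript is the genomic hull of its CDS features.  Transcripts with
    no exon features are dropped with a warning.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted dialect errors
        raise FormatError(f"cannot parse GTF {path}: {exc}") from None

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    for ftype, sink in (("exon", exons), ("CDS", cds)):
        for feat in db.features_of_type(ftype):
            tx = _attr(feat, "transcript_id")
            if tx is None:
                raise FormatError(
                    f"{path}: {ftype} feature without transcript_id at "
                    f"{feat.seqid}:{feat.start}"
                )
            sink.setdefault(tx, []).append((feat.start - 1, feat.end))
            if tx not in meta:
                gene_id = _attr(feat, "gene_id") or tx
                tags = feat.attributes.get("tag", [])
                meta[tx] = {
                    "gene_id": gene_id,
                    "gene_name": _attr(feat, "gene_name") or gene_id,
                    "chrom": normalize_chrom(feat.seqid),
                    "strand": feat.strand,
                    "canonical": any("canonical" in t.lower() for t in tags),
                }
            elif any("canonical" in t.lower() for t in feat.attributes.get("tag", [])):
                meta[tx]["canonical"] = True

    store = GeneModelStore()
    for tx, spans in cds.items():
        if tx not in exons:
            logger.warning("transcript %s has CDS but no exon features; dropped", tx)
    for tx, ex in exons.items():
        m = meta[tx]
        cds_span = None
        if tx in cds:
            cds_span = (min(s for s, _ in cds[tx]), max(e for _, e in cds[tx]))
        store.add(
            TranscriptModel(
                transcript_id=tx,
                gene_id=m["gene_id"],
                gene_name=m["gene_name"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=ex,
                cds_span=cds_span,
                canonical=m["canonical"],
            )
        )
    return store


def select_isoform(
    store: GeneModelStore, gene: str, user_choice: str | None = None
) -> TranscriptModel:
    """Pick the single isoform used for fusion reconstruction.

    An explicit ``user_choice`` accession wins (it must belong to the gene).
    Otherwise the representative isoform is chosen deterministically:
    canonical tag > longest CDS > longest spliced length > lexicographically
    smallest accession.
    """
    isoforms = store.transcripts_of(gene)
    if user_choice is not None:
        for tm in isoforms:
            if tm.transcript_id == user_choice:
                return tm
        raise ValueError(
            f"transcript {user_choice!r} is not an isoform of gene {gene!r}"
        )
    return min(
        isoforms,
        key=lambda t: (
            not t.canonical,
            -t.cds_length,
            -t.spliced_length,
            t.transcript_id,
        ),
    )


def exon_ordinal(transcript: TranscriptModel, genomic_pos: int) -> int | str:
    """1-based exon number in transcription order, or ``"intronic"``.

    For '-'-strand transcripts exon 1 is the exon with the largest genomic
    coordinates.  Positions outside the transcript hull raise ``ValueError``.
    """
    lo, hi = transcript.hull
    if not lo <= genomic_pos < hi:
        raise ValueError(
            f"position {genomic_pos} outside hull [{lo},{hi}) of "
            f"{transcript.transcript_id}"
        )
    for i, (s, e) in enumerate(transcript.exons_transcription_order(), start=1):
        if s <= genomic_pos < e:
            return i
    return INTRONIC
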