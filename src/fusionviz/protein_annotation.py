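"""Reading-frame inference, translation and domain remapping.

The chimeric transcript is translated from the 5' partner's annotated start
codon.  The fusion is in frame when the number of retained 5' coding
nucleotides and the junction's offset within the 3' partner's own CDS agree
modulo 3 — i.e. the 3' codons keep their native phase — and translation
reaches the junction without a premature stop.  Out-of-frame fusions
terminate at the first stop codon encountered in the shifted frame.

Partner protein domains (1-based inclusive amino-acid intervals keyed by
transcript accession) are remapped onto the fusion peptide: 5' domains map
by identity and are clipped at the junction; 3' domains shift by the net
amino-acid offset and are clipped to the retained region.  Domains cut by
the junction or the termination site are kept with their retained fraction
rather than dropped, since partial loss of a domain is exactly what the
domain plot is meant to show.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .fusion_builder import FusionTranscript
from .gene_models import TranscriptModel
from .io_formats import DomainTableRow

logger = logging.getLogger(__name__)

__all__ = [
    "FrameStatus",
    "FusionProtein",
    "RemappedDomain",
    "determine_frame",
    "translate_fusion",
    "remap_domains",
    "native_protein",
    "cds_spliced_bounds",
]

IN_FRAME = "in_frame"
OUT_OF_FRAME = "out_of_frame"
NO_CDS = "no_cds"

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class FrameStatus:
    """Outcome of reading-frame inference for one fusion transcript."""

    status: str  # in_frame | out_of_frame | no_cds
    translation_start_cdna: int = 0
    termination_cdna: int | None = None
    reason: str = ""
    #: retained 5'-partner coding nucleotides (junction_offset - start codon)
    retained_five_cds: int | None = None
    #: junction entry offset within the 3' partner's own spliced CDS
    three_cds_offset: int | None = None


@dataclass
class RemappedDomain:
    """A partner domain re-expressed in fusion-peptide coordinates."""

    name: str
    source_gene: str
    start_aa: int  # 1-based inclusive, on the fusion peptide
    end_aa: int
    retained_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.retained_fraction <= 1.0:
            raise ValueError("retained_fraction must be in (0, 1]")


@dataclass
class FusionProtein:
    """Translated chimeric peptide with junction position and domains."""

    peptide: str
    junction_aa: int  # 1-based position of the last 5'-derived residue
    n_terminus_source: str
    c_terminus_source: str  # 3' gene symbol, or "truncated"
    domains: list[RemappedDomain] = field(default_factory=list)


def cds_spliced_bounds(model: TranscriptModel) -> tuple[int, int] | None:
    """(start, end) spliced offsets of the CDS, half-open, transcription order."""
    if model.cds_span is None:
        return None
    cs, ce = model.cds_span
    first = cs if model.strand == "+" else ce - 1
    last = ce - 1 if model.strand == "+" else cs
    return model.genomic_to_spliced(first), model.genomic_to_spliced(last) + 1


def _first_stop(cdna: str, start: int) -> int | None:
    """cDNA offset of the first stop codon in frame with ``start``."""
    for pos in range(start, len(cdna) - 2, 3):
        if cdna[pos : pos + 3] in _STOPS:
            return pos
    return None


def spliced_sequence(model: TranscriptModel, genome) -> str:
    """Full spliced transcript sequence in transcription order."""
    parts = []
    for s, e in model.exons:
        parts.append(str(genome[_fasta_key(genome, model.chrom)][s:e]).upper())
    seq = "".join(parts)
    return seq if model.strand == "+" else str(Seq(seq).reverse_complement())


def _fasta_key(genome, chrom: str) -> str:
    for cand in (chrom, f"chr{chrom}"):
        try:
            genome[cand]
            return cand
        except KeyError:
            continue
    raise KeyError(f"chromosome {chrom!r} absent from genome")


def native_protein(model: TranscriptModel, genome) -> str:
    """Translate a transcript's own CDS (no stop symbol)."""
    bounds = cds_spliced_bounds(model)
    if bounds is None:
        raise ValueError(f"{model.transcript_id} is non-coding")
    spliced = spliced_sequence(model, genome)
    cds = spliced[bounds[0] : bounds[1]]
    cds = cds[: len(cds) // 3 * 3]
    return str(Seq(cds).translate(table=1, to_stop=True))


def determine_frame(
    ft: FusionTranscript,
    five_model: TranscriptModel | None = None,
    three_model: TranscriptModel | None = None,
) -> FrameStatus:
    """Classify a fusion transcript as in-frame, out-of-frame or non-coding.

    The models default to the ones the transcript was built from.  A 5'
    breakpoint upstream of the 5' partner's start codon yields ``no_cds``
    with reason ``junction_in_5'UTR`` (no alternative-ATG scanning is
    attempted).
    """
    five_model = five_model or ft.five_model
    three_model = three_model or ft.three_model

    bounds5 = cds_spliced_bounds(five_model)
    if bounds5 is None:
        return FrameStatus(NO_CDS, reason="non-coding 5' partner")
    tstart, cds5_end = bounds5
    if tstart >= ft.junction_offset:
        logger.warning(
            "%s: junction upstream of the 5' start codon; reported untranslated",
            ft.candidate.name,
        )
        return FrameStatus(
            NO_CDS, translation_start_cdna=tstart, reason="junction_in_5'UTR"
        )

    retained5_cds = ft.junction_offset - tstart

    # Junction entry point on the 3' partner, in its own spliced CDS frame.
    three_offset: int | None = None
    bounds3 = cds_spliced_bounds(three_model)
    if bounds3 is not None:
        first3 = ft.three_segments[0]
        s, e = first3.genomic_interval
        entry_genomic = s if three_model.strand == "+" else e - 1
        three_offset = three_model.genomic_to_spliced(entry_genomic) - bounds3[0]

    phase_ok = three_offset is not None and (retained5_cds - three_offset) % 3 == 0

    stop = _first_stop(ft.cdna, tstart)
    premature = stop is not None and stop + 3 <= ft.junction_offset
    if phase_ok and not premature:
        return FrameStatus(
            IN_FRAME,
            translation_start_cdna=tstart,
            termination_cdna=stop,
            retained_five_cds=retained5_cds,
            three_cds_offset=three_offset,
        )
    reason = "premature stop before junction" if premature else "phase shift"
    return FrameStatus(
        OUT_OF_FRAME,
        translation_start_cdna=tstart,
        termination_cdna=stop,
        reason=reason,
        retained_five_cds=retained5_cds,
        three_cds_offset=three_offset,
    )


def translate_fusion(ft: FusionTranscript, fs: FrameStatus) -> FusionProtein:
    """Translate the chimeric cDNA from the 5' partner's start codon.

    The peptide stops at (and excludes) the first stop codon, or runs to the
    cDNA end.  ``junction_aa`` is the 1-based position of the last residue
    containing 5'-derived sequence (a hybrid codon counts as 5'-derived).
    """
    if fs.status == NO_CDS:
        raise ValueError(f"cannot translate a {NO_CDS} fusion ({fs.reason})")
    coding = ft.cdna[fs.translation_start_cdna :]
    coding = coding[: len(coding) // 3 * 3]
    peptide = str(Seq(coding).translate(table=1, to_stop=True))
    if "X" in peptide:
        logger.warning("%s: ambiguous (N) codons in fusion peptide", ft.candidate.name)
    junction_aa = math.ceil((ft.junction_offset - fs.translation_start_cdna) / 3)
    junction_aa = min(junction_aa, len(peptide) + 1)
    c_source = (
        ft.candidate.three_gene if fs.status == IN_FRAME else "truncated"
    )
    return FusionProtein(
        peptide=peptide,
        junction_aa=junction_aa,
        n_terminus_source=ft.candidate.five_gene,
        c_terminus_source=c_source,
    )


def _matches(row_id: str, model: TranscriptModel) -> bool:
    return row_id in {model.transcript_id, model.gene_name, model.gene_id}


def remap_domains(
    fp: FusionProtein,
    fs: FrameStatus,
    domains: list[DomainTableRow],
    five_model: TranscriptModel,
    three_model: TranscriptModel,
) -> list[RemappedDomain]:
    """Re-express partner domains in fusion-peptide coordinates.

    5' domains keep their native coordinates (same start codon) clipped at
    the junction; 3' domains (in-frame fusions only) shift by
    ``(retained 5' CDS nt − 3' entry offset) / 3`` amino acids and are
    clipped to the fully 3'-derived region.  Domains left with zero retained
    residues are dropped; rows keyed to neither partner are skipped with a
    warning.
    """
    out: list[RemappedDomain] = []
    n = len(fp.peptide)
    for row in domains:
        if _matches(row.protein_or_transcript_id, five_model):
            start = row.start_aa
            end = min(row.end_aa, fp.junction_aa, n)
            if start > end:
                continue
            full = row.end_aa - row.start_aa + 1
            out.append(
                RemappedDomain(
                    name=row.domain_name,
                    source_gene=five_model.gene_name,
                    start_aa=start,
                    end_aa=end,
                    retained_fraction=(end - start + 1) / full,
                )
            )
        elif _matches(row.protein_or_transcript_id, three_model):
            if fs.status != IN_FRAME:
                continue  # shifted frame: no native 3' residues exist
            shift = (fs.retained_five_cds - fs.three_cds_offset) // 3
            start = max(row.start_aa + shift, fp.junction_aa + 1)
            end = min(row.end_aa + shift, n)
            if start > end:
                continue
            full = row.end_aa - row.start_aa + 1
            out.append(
                RemappedDomain(
                    name=row.domain_name,
                    source_gene=three_model.gene_name,
                    start_aa=start,
                    end_aa=end,
                    retained_fraction=(end - start + 1) / full,
                )
            )
        else:
            logger.warning(
                "domain %s keyed by %r matches neither fusion partner; skipped",
                row.domain_name, row.protein_or_transcript_id,
            )
    return sorted(out, key=lambda d: (d.start_aa, d.end_aa, d.name))
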