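"""Batch orchestration: BEDPE in, annotated TSV + PDFs out.

Processes every fusion candidate in a BEDPE file against the gene models,
genome and (optionally) BAM/domain/ideogram inputs, producing the requested
plot types for every viable isoform pair plus one sidecar TSV row per pair.
Candidates that cannot be annotated (gene missing from the GTF, breakpoint
outside every isoform, ...) are skipped with a logged reason rather than
aborting the batch.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

import pyfaidx

from . import fusion_builder, gene_models, io_formats, protein_annotation
from .expression import compute_coverage, flag_fusion_positive, normalize_expression
from .gene_models import GeneModelStore, exon_ordinal, select_isoform
from .rendering import (
    PlotStyle,
    render_cohort_expression,
    render_domain,
    render_exon_expression,
    render_structure,
)

logger = logging.getLogger(__name__)

STRUCTURE, DOMAIN, EXON_EXPR, GENE_EXPR = (
    "structure", "domain", "exon-expression", "gene-expression",
)


def _safe_name(fusion_name: str) -> str:
    return fusion_name.replace(">>", "--")


def _isoform_pairs(candidate, store: GeneModelStore, tx5, tx3):
    if tx5 or tx3:
        return [(
            select_isoform(store, candidate.five_gene, tx5),
            select_isoform(store, candidate.three_gene, tx3),
        )]
    return fusion_builder.enumerate_isoform_pairs(candidate, store)


def process_sample(
    bedpe_path: str | Path,
    gtf_path: str | Path,
    fasta_path: str | Path,
    out_dir: str | Path,
    plots: set[str],
    bam_path: str | Path | None = None,
    domains_path: str | Path | None = None,
    ideogram_path: str | Path | None = None,
    style: PlotStyle | None = None,
    tx5: str | None = None,
    tx3: str | None = None,
    mapq: int = 0,
    ymax: float | None = None,
) -> tuple[list[Path], Path]:
    """Annotate and plot every fusion in a single-sample BEDPE.

    Returns (written PDF paths, sidecar TSV path).
    """
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    style = style or PlotStyle()
    store = gene_models.parse_gtf(str(gtf_path))
    genome = pyfaidx.Fasta(str(fasta_path))
    records = io_formats.read_bedpe(bedpe_path)
    domain_rows = (
        io_formats.read_domain_table(domains_path) if domains_path else []
    )
    ideogram = (
        io_formats.read_ideogram(ideogram_path) if ideogram_path else []
    )

    written: list[Path] = []
    sidecar_rows: list[dict] = []
    for rec in records:
        try:
            candidate = fusion_builder.candidate_from_bedpe(rec, store)
            pairs = _isoform_pairs(candidate, store, tx5, tx3)
        except (KeyError, ValueError) as exc:
            logger.warning("skipping %s: %s", rec.name, exc)
            continue
        for five_model, three_model in pairs:
            try:
                outputs = _process_pair(
                    candidate, five_model, three_model, genome, store,
                    domain_rows, ideogram, plots, bam_path, style, mapq,
                    ymax, out_dir, sidecar_rows,
                )
                written.extend(outputs)
            except (KeyError, ValueError) as exc:
                logger.warning(
                    "skipping %s (%s x %s): %s", rec.name,
                    five_model.transcript_id, three_model.transcript_id, exc,
                )
            finally:
                plt.close("all")
    sidecar = out_dir / "annotated_fusions.tsv"
    io_formats.write_annotation_table(sidecar_rows, sidecar)
    return written, sidecar


def _process_pair(
    candidate, five_model, three_model, genome, store, domain_rows,
    ideogram, plots, bam_path, style, mapq, ymax, out_dir, sidecar_rows,
) -> list[Path]:
    ft = fusion_builder.build_fusion_transcript(
        candidate, five_model, three_model, genome
    )
    fs = protein_annotation.determine_frame(ft)
    fp = None
    if fs.status != protein_annotation.NO_CDS:
        fp = protein_annotation.translate_fusion(ft, fs)
        fp.domains = protein_annotation.remap_domains(
            fp, fs, domain_rows, five_model, three_model
        )

    base = (
        f"{_safe_name(candidate.name)}."
        f"{five_model.transcript_id}.{three_model.transcript_id}"
    )
    written: list[Path] = []
    if STRUCTURE in plots:
        path = out_dir / f"{base}.structure.pdf"
        render_structure(ft, ideogram, style, path)
        written.append(path)
    if DOMAIN in plots:
        if fp is None:
            logger.warning(
                "%s (%s): no domain plot — %s", candidate.name, base, fs.reason
            )
        else:
            path = out_dir / f"{base}.domain.pdf"
            render_domain(fp, fs, style, path)
            written.append(path)
    if EXON_EXPR in plots:
        if bam_path is None:
            raise ValueError("exon-expression plot requires a BAM file")
        track5 = compute_coverage(str(bam_path), five_model,
                                  candidate.five_pos, mapq=mapq)
        track3 = compute_coverage(str(bam_path), three_model,
                                  candidate.three_pos, mapq=mapq)
        path = out_dir / f"{base}.exon_expression.pdf"
        override = {"ymax": ymax} if ymax else None
        render_exon_expression((track5, track3), style, path, override)
        written.append(path)

    sidecar_rows.append({
        "fusion": candidate.name,
        "tx5": five_model.transcript_id,
        "tx3": three_model.transcript_id,
        "junction_exon5": exon_ordinal(five_model, candidate.five_pos),
        "junction_exon3": exon_ordinal(three_model, candidate.three_pos),
        "frame_status": fs.status,
        "junction_offset": ft.junction_offset,
        "cdna_length": len(ft.cdna),
        "retained_domains": ";".join(
            f"{d.name}:{d.start_aa}-{d.end_aa}({d.retained_fraction:.3g})"
            for d in (fp.domains if fp else [])
        ),
    })
    return written


def cohort_bedpe_by_sample(path: str | Path) -> dict[str, list]:
    """Group a cohort BEDPE's records by their sample-id column."""
    grouped: dict[str, list] = defaultdict(list)
    for rec in io_formats.read_bedpe(path):
        sample = rec.sample_id
        if sample is None:
            logger.warning("cohort record %s lacks a sample id; ignored", rec.name)
            continue
        grouped[sample].append(rec)
    return dict(grouped)


def process_cohort(
    bedpe_path: str | Path,
    counts_path: str | Path,
    out_dir: str | Path,
    highlight_sample: str | None = None,
    style: PlotStyle | None = None,
) -> list[Path]:
    """Cohort gene-expression plots for every distinct fusion pair.

    Expression is FPKM from the count matrix; samples are flagged
    fusion-positive per ordered gene pair from the cohort BEDPE.
    """
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    style = style or PlotStyle()
    cm = io_formats.read_count_matrix(counts_path)
    grouped = cohort_bedpe_by_sample(bedpe_path)
    pairs = sorted({
        (rec.gene5, rec.gene3)
        for recs in grouped.values() for rec in recs
    })
    written: list[Path] = []
    for gene5, gene3 in pairs:
        try:
            table = normalize_expression(cm, (gene5, gene3))
        except KeyError as exc:
            logger.warning("skipping cohort plot %s>>%s: %s", gene5, gene3, exc)
            continue
        table = flag_fusion_positive(table, grouped)
        path = out_dir / f"{gene5}--{gene3}.gene_expression.pdf"
        render_cohort_expression(table, highlight_sample, style, path)
        plt.close("all")
        written.append(path)
    return written
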