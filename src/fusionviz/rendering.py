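"""The four PDF plot types: structure, domain, exon expression, cohort.

Conventions follow the tool's fixed palette: blue for everything deriving
from the 5' partner (reads, exons, transcript, genomic locus), red for the
3' partner; the fusion junction is a red vertical line and exon boundaries
are blue lines in the coverage panels.  All renderers are deterministic —
the same inputs produce the same drawing primitives — and PDF output is
written without a creation timestamp so repeated runs are byte-comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.lines import Line2D
from matplotlib.patches import FancyBboxPatch, Rectangle

from .expression import CohortExpressionTable, CoverageTrack
from .fusion_builder import FusionTranscript, glyph_count
from .io_formats import IdeogramBand, normalize_chrom
from .protein_annotation import OUT_OF_FRAME, FrameStatus, FusionProtein

logger = logging.getLogger(__name__)

__all__ = [
    "PlotStyle",
    "nice_ceiling",
    "render_structure",
    "render_domain",
    "render_exon_expression",
    "render_cohort_expression",
]

_SAVE_KW = {"metadata": {"CreationDate": None}}

_STAIN_GRAY = {
    "gneg": "0.97",
    "gpos25": "0.8",
    "gpos50": "0.6",
    "gpos75": "0.4",
    "gpos100": "0.15",
    "acen": "firebrick",
    "gvar": "0.85",
    "stalk": "0.7",
}


@dataclass
class PlotStyle:
    """Colors and page parameters shared by all four plot types."""

    five_prime_color: str = "blue"
    three_prime_color: str = "red"
    junction_line_color: str = "red"
    exon_boundary_color: str = "blue"
    neutral_color: str = "0.6"
    page_width: float = 8.5
    page_height: float = 6.0
    font_size: float = 8.0

    @classmethod
    def from_file(cls, path: str | Path) -> "PlotStyle":
        """Load overrides from a key=value text file (unknown keys ignored)."""
        style = cls()
        fields = set(style.__dataclass_fields__)
        overrides = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, value = (t.strip() for t in line.split("=", 1))
                if key not in fields:
                    logger.warning("unknown style key %r ignored", key)
                    continue
                cur = getattr(style, key)
                overrides[key] = type(cur)(value) if isinstance(cur, float) else value
        return replace(style, **overrides)


def nice_ceiling(x: float) -> float:
    """Smallest 1/2/5 x 10^k value >= x (the auto axis maximum)."""
    if x <= 0:
        return 1.0
    k = np.floor(np.log10(x))
    for mult in (1.0, 2.0, 5.0, 10.0):
        cand = mult * 10.0 ** k
        if cand >= x or np.isclose(cand, x):
            return cand
    return 10.0 ** (k + 1)


def _save(fig, out: str | Path | None):
    if out is not None:
        fig.savefig(out, format="pdf", **_SAVE_KW)
    return fig


def _ideogram_lane(ax, bands: list[IdeogramBand], loci: list[tuple[str, int, str]],
                   style: PlotStyle) -> None:
    """Chromosome bars with Giemsa bands; partner loci marked by triangles."""
    chroms: dict[str, list[IdeogramBand]] = {}
    for b in bands:
        chroms.setdefault(normalize_chrom(b.chrom), []).append(b)
    n = max(len(chroms), 1)
    for row, (chrom, cbands) in enumerate(sorted(chroms.items())):
        length = max(b.end for b in cbands)
        y = n - 1 - row
        for b in cbands:
            ax.add_patch(Rectangle(
                (b.start / length, y + 0.25), (b.end - b.start) / length, 0.35,
                facecolor=_STAIN_GRAY.get(b.stain, "0.9"), edgecolor="black",
                linewidth=0.4,
            ))
        ax.text(-0.01, y + 0.42, f"chr{chrom}", ha="right", va="center",
                fontsize=style.font_size)
        for locus_chrom, pos, color in loci:
            if normalize_chrom(locus_chrom) == chrom:
                ax.plot([pos / length], [y + 0.72], marker="v", color=color,
                        markersize=5, clip_on=False)
    ax.set_xlim(-0.12, 1.02)
    ax.set_ylim(0, n + 0.2)
    ax.axis("off")


def _gene_track(ax, model, breakpoint: int, color: str, style: PlotStyle) -> None:
    lo, hi = model.hull
    width = hi - lo

    def x(pos):
        return (pos - lo) / width

    ax.plot([0, 1], [0.5, 0.5], color="black", linewidth=0.8, zorder=1)
    for s, e in model.exons:
        ax.add_patch(Rectangle((x(s), 0.3), x(e) - x(s), 0.4, facecolor=color,
                               edgecolor="black", linewidth=0.4, zorder=2))
    ax.axvline(x(breakpoint), color=style.junction_line_color, linewidth=1.2,
               zorder=3)
    arrow = ">" if model.strand == "+" else "<"
    ax.text(-0.01, 0.5,
            f"{model.gene_name} ({model.transcript_id}) {arrow}",
            ha="right", va="center", fontsize=style.font_size)
    ax.set_xlim(-0.35, 1.02)
    ax.set_ylim(0, 1)
    ax.axis("off")


def _fusion_lane(ax, ft: FusionTranscript, style: PlotStyle) -> None:
    total = len(ft.cdna)
    xpos = 0
    for seg in ft.segments:
        color = (style.five_prime_color if seg.source == "five_prime"
                 else style.three_prime_color)
        ax.add_patch(Rectangle((xpos / total, 0.35), seg.length / total, 0.3,
                               facecolor=color, edgecolor="black",
                               linewidth=0.4))
        xpos += seg.length
    jx = ft.junction_offset / total
    ax.axvline(jx, color=style.junction_line_color, linewidth=1.2)
    label = "fusion transcript"
    if ft.snapped:
        label += " (junction snapped)"
    ax.text(-0.01, 0.5, label, ha="right", va="center", fontsize=style.font_size)

    # Supporting-read glyphs: spanning reads cross the junction as a single
    # two-colored bar; encompassing pairs sit on either side with a dashed
    # link.  One gid'ed backbone line per glyph.
    n_span = glyph_count(ft.candidate.spanning_reads)
    n_enc = glyph_count(ft.candidate.encompassing_reads)
    y = 0.78
    for i in range(n_span):
        half = 0.06
        ax.plot([jx - half, jx], [y, y], color=style.five_prime_color,
                linewidth=2.5, solid_capstyle="butt")
        ax.plot([jx, jx + half], [y, y], color=style.three_prime_color,
                linewidth=2.5, solid_capstyle="butt")
        backbone = Line2D([jx - half, jx + half], [y, y], alpha=0.0)
        backbone.set_gid(f"read-glyph-span-{i}")
        ax.add_line(backbone)
        y += 0.14
    y = 0.78
    for i in range(n_enc):
        gap = 0.10
        ax.plot([jx - gap - 0.05, jx - gap], [y, y],
                color=style.five_prime_color, linewidth=2.5)
        ax.plot([jx + gap, jx + gap + 0.05], [y, y],
                color=style.three_prime_color, linewidth=2.5)
        ax.plot([jx - gap, jx + gap], [y, y], color="0.6", linewidth=0.8,
                linestyle=":")
        backbone = Line2D([jx - gap - 0.05, jx + gap + 0.05], [y, y], alpha=0.0)
        backbone.set_gid(f"read-glyph-enc-{i}")
        ax.add_line(backbone)
        y += 0.14
    ax.set_xlim(-0.35, 1.02)
    ax.set_ylim(0, 1.3)
    ax.axis("off")


def render_structure(
    ft: FusionTranscript,
    ideogram: list[IdeogramBand],
    style: PlotStyle | None = None,
    out: str | Path | None = None,
):
    """Structure plot: ideogram, partner gene tracks, fused transcript, reads.

    An empty ideogram list omits the ideogram lane.  Returns the figure
    (also written to ``out`` as PDF when given).
    """
    style = style or PlotStyle()
    cand = ft.candidate
    have_ideo = bool(ideogram)
    nrows = 4 if have_ideo else 3
    heights = ([1.2] if have_ideo else []) + [0.8, 0.8, 1.4]
    fig, axes = plt.subplots(
        nrows, 1, figsize=(style.page_width, style.page_height),
        gridspec_kw={"height_ratios": heights},
    )
    axes = np.atleast_1d(axes)
    row = 0
    if have_ideo:
        loci = [
            (cand.five_chrom, cand.five_pos, style.five_prime_color),
            (cand.three_chrom, cand.three_pos, style.three_prime_color),
        ]
        _ideogram_lane(axes[row], ideogram, loci, style)
        row += 1
    _gene_track(axes[row], ft.five_model, cand.five_pos,
                style.five_prime_color, style)
    _gene_track(axes[row + 1], ft.three_model, cand.three_pos,
                style.three_prime_color, style)
    _fusion_lane(axes[row + 2], ft, style)
    fig.suptitle(
        f"{cand.name}  (spanning {cand.spanning_reads}, "
        f"encompassing {cand.encompassing_reads})",
        fontsize=style.font_size + 2,
    )
    return _save(fig, out)


def render_domain(
    fp: FusionProtein,
    fs: FrameStatus,
    style: PlotStyle | None = None,
    out: str | Path | None = None,
):
    """Domain plot: fusion peptide bar with remapped domains.

    The 5' region is drawn in the 5' color with an N label at the left, the
    3' region in the 3' color with a C label at the right.  For out-of-frame
    fusions the region after the junction is a white (empty) box ending in a
    red cross at the translation termination site; no 3' domains are drawn.
    """
    style = style or PlotStyle()
    n = max(len(fp.peptide), 1)
    fig, ax = plt.subplots(figsize=(style.page_width, style.page_height * 0.45))

    def x(aa):  # 1-based aa -> axis fraction
        return (aa - 1) / n

    j = min(fp.junction_aa, n)
    ax.add_patch(Rectangle((0, 0.4), x(j + 1), 0.2,
                           facecolor=style.five_prime_color, alpha=0.45,
                           edgecolor="black", linewidth=0.6))
    if fs.status == OUT_OF_FRAME:
        ax.add_patch(Rectangle((x(j + 1), 0.4), 1 - x(j + 1), 0.2,
                               facecolor="white", edgecolor="black",
                               linewidth=0.6))
        cross, = ax.plot([1.0], [0.5], marker="x", color="red", markersize=10,
                         markeredgewidth=2.5, clip_on=False)
        cross.set_gid("termination-cross")
    else:
        ax.add_patch(Rectangle((x(j + 1), 0.4), 1 - x(j + 1), 0.2,
                               facecolor=style.three_prime_color, alpha=0.45,
                               edgecolor="black", linewidth=0.6))
    ax.axvline(x(j + 1), color=style.junction_line_color, linewidth=1.0)
    for dom in fp.domains:
        color = (style.five_prime_color
                 if dom.source_gene == fp.n_terminus_source
                 else style.three_prime_color)
        patch = FancyBboxPatch(
            (x(dom.start_aa), 0.36), x(dom.end_aa + 1) - x(dom.start_aa), 0.28,
            boxstyle="round,pad=0.004", facecolor=color, edgecolor="black",
            linewidth=0.7,
        )
        patch.set_gid(f"domain-{dom.name}")
        ax.add_patch(patch)
        ax.text((x(dom.start_aa) + x(dom.end_aa + 1)) / 2, 0.5, dom.name,
                ha="center", va="center", fontsize=style.font_size,
                color="white")
    ax.text(-0.015, 0.5, "N", ha="right", va="center",
            fontsize=style.font_size + 2, fontweight="bold")
    ax.text(1.015, 0.5, "C", ha="left", va="center",
            fontsize=style.font_size + 2, fontweight="bold")
    ax.text(0, 0.75, fp.n_terminus_source, color=style.five_prime_color,
            fontsize=style.font_size)
    ax.text(1, 0.75, fp.c_terminus_source, color=style.three_prime_color,
            ha="right", fontsize=style.font_size)
    ax.text(0.5, 0.12, f"{n} aa; junction at aa {fp.junction_aa}",
            ha="center", fontsize=style.font_size)
    ax.set_xlim(-0.06, 1.06)
    ax.set_ylim(0, 1)
    ax.axis("off")
    return _save(fig, out)


def render_exon_expression(
    tracks: tuple[CoverageTrack, CoverageTrack],
    style: PlotStyle | None = None,
    out: str | Path | None = None,
    axis_override: dict | None = None,
):
    """Exon expression plot: per-base depth for both partners, one panel each.

    Each panel fills the depth curve, draws a red vertical line at the
    fusion junction and blue lines at exon boundaries, and auto-scales its
    y-axis to the next "nice" (1/2/5 x 10^k) value above the observed
    maximum unless ``axis_override`` supplies ``ymax`` / per-panel ranges.
    """
    style = style or PlotStyle()
    axis_override = axis_override or {}
    fig, axes = plt.subplots(2, 1, figsize=(style.page_width, style.page_height))
    colors = (style.five_prime_color, style.three_prime_color)
    for ax, track, color in zip(axes, tracks, colors):
        lo, hi = track.span
        xs = np.arange(lo, hi)
        ax.fill_between(xs, track.depth, step="mid", color=color, alpha=0.6,
                        linewidth=0)
        maxdepth = int(track.depth.max()) if len(track.depth) else 0
        if maxdepth == 0:
            logger.warning("all-zero coverage for %s; flat track", track.gene)
        ymax = axis_override.get("ymax") or nice_ceiling(maxdepth)
        for b in track.exon_boundaries:
            ax.axvline(b, color=style.exon_boundary_color, linewidth=0.5,
                       alpha=0.7)
        ax.axvline(track.junction_pos, color=style.junction_line_color,
                   linewidth=1.3)
        xmin, xmax = axis_override.get("xrange", (lo, hi))
        ax.set_xlim(xmin, xmax)
        ax.set_ylim(0, ymax)
        ax.set_ylabel("read depth", fontsize=style.font_size)
        ax.set_title(f"{track.gene} (chr{track.chrom})",
                     fontsize=style.font_size + 1)
        ax.tick_params(labelsize=style.font_size - 1)
    axes[-1].set_xlabel("genomic position", fontsize=style.font_size)
    fig.tight_layout()
    return _save(fig, out)


def render_cohort_expression(
    table: CohortExpressionTable,
    highlight_sample: str | None = None,
    style: PlotStyle | None = None,
    out: str | Path | None = None,
):
    """Cohort plot: one bar per sample for each partner gene.

    Samples are sorted by the 3' gene's expression; fusion-positive samples
    are drawn in the 3' color, fusion-negative in gray, and the highlighted
    sample gets a black edge and a marker above its bars.
    """
    style = style or PlotStyle()
    df = table.data.sort_values(
        [table.gene3, "sample_id"], kind="mergesort"
    ).reset_index(drop=True)
    if highlight_sample is not None and highlight_sample not in set(df["sample_id"]):
        logger.warning("highlight sample %r absent from cohort", highlight_sample)
        highlight_sample = None
    fig, axes = plt.subplots(2, 1, figsize=(style.page_width, style.page_height),
                             sharex=True)
    xs = np.arange(len(df))
    for ax, gene in zip(axes, (table.gene5, table.gene3)):
        colors = [
            style.three_prime_color if pos else style.neutral_color
            for pos in df["fusion_positive"]
        ]
        edges = [
            "black" if s == highlight_sample else "none"
            for s in df["sample_id"]
        ]
        bars = ax.bar(xs, df[gene], color=colors, edgecolor=edges, linewidth=1.2)
        for i, (bar, s) in enumerate(zip(bars, df["sample_id"])):
            bar.set_gid(f"bar-{gene}-{s}")
            if s == highlight_sample:
                ax.plot([i], [float(df[gene].iloc[i]) * 1.04 + 0.01], marker="v",
                        color="black", markersize=5)
        ax.set_ylabel(f"{gene} ({table.unit})", fontsize=style.font_size)
        ax.tick_params(labelsize=style.font_size - 1)
    axes[-1].set_xticks(xs)
    axes[-1].set_xticklabels(df["sample_id"], rotation=90,
                             fontsize=max(style.font_size - 3, 4))
    n_pos = int(df["fusion_positive"].sum())
    fig.suptitle(
        f"{table.gene5}>>{table.gene3}: {n_pos}/{len(df)} fusion-positive samples",
        fontsize=style.font_size + 2,
    )
    fig.tight_layout()
    return _save(fig, out)
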