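"""Readers and writers for the external file formats the tool touches.

Fusion candidates arrive as BEDPE (tab-separated, two genomic intervals plus
name/score/strands, ``#`` comments allowed); protein domains and cytogenetic
ideogram bands as TSV tables; gene-level read counts as a FeatureCounts-style
gene-by-sample TSV.  All genomic intervals are 0-based half-open (BED
convention); amino-acid coordinates are 1-based inclusive (UniProt/Pfam
convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BedpeRecord",
    "DomainTableRow",
    "IdeogramBand",
    "CountMatrix",
    "FormatError",
    "read_bedpe",
    "write_bedpe",
    "read_domain_table",
    "read_ideogram",
    "read_count_matrix",
    "write_annotation_table",
    "normalize_chrom",
]

_VALID_STRANDS = {"+", "-", "."}

#: Header-comment tokens that mark trailing BEDPE columns carrying
#: junction-supporting read counts and a sample identifier.  The BEDPE
#: standard mandates no such columns, so their presence is signalled by a
#: comment line such as ``#chrom1 ... strand2  spanning  encompassing  sample``.
EXTRA_COLUMN_KEYS = ("spanning", "encompassing", "sample")


class FormatError(ValueError):
    """A malformed input file (wrong column count, bad coordinate, ...)."""


def normalize_chrom(name: str) -> str:
    """Harmonize chromosome naming by stripping any ``chr`` prefix.

    BEDPE, GTF, FASTA and BAM inputs routinely disagree about the prefix;
    all lookups in this package go through this normalization.
    """
    return name[3:] if name.lower().startswith("chr") else name


@dataclass
class BedpeRecord:
    """One fusion candidate: a pair of genomic breakpoint intervals.

    ``name`` follows the ``GENE5>>GENE3`` convention (5' partner first).
    ``extra`` holds any trailing columns beyond the 10 standard ones, in file
    order; ``extra_labels`` holds their header names when a labelled header
    comment was present.
    """

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    name: str
    score: str = "."
    strand1: str = "."
    strand2: str = "."
    extra: list[str] = field(default_factory=list)
    extra_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.start1 < self.end1 and self.start2 < self.end2):
            raise FormatError(
                f"BEDPE intervals must be non-empty half-open: {self}"
            )
        if self.strand1 not in _VALID_STRANDS or self.strand2 not in _VALID_STRANDS:
            raise FormatError(
                f"strand must be one of {{+,-,.}}, got {self.strand1!r}/{self.strand2!r}"
            )

    @property
    def gene5(self) -> str:
        return self.name.split(">>")[0] if ">>" in self.name else self.name

    @property
    def gene3(self) -> str:
        return self.name.split(">>")[1] if ">>" in self.name else ""

    def _labelled_extra(self, key: str) -> str | None:
        for label, value in zip(self.extra_labels, self.extra):
            if key in label.lower():
                return value
        return None

    @property
    def spanning_reads(self) -> int:
        """Junction-spanning read count from a labelled extra column, else 0."""
        v = self._labelled_extra("spanning")
        return int(v) if v is not None else 0

    @property
    def encompassing_reads(self) -> int:
        """Junction-encompassing read-pair count from a labelled column, else 0."""
        v = self._labelled_extra("encompassing")
        return int(v) if v is not None else 0

    @property
    def sample_id(self) -> str | None:
        return self._labelled_extra("sample")

    def to_line(self) -> str:
        cols = [
            self.chrom1, str(self.start1), str(self.end1),
            self.chrom2, str(self.start2), str(self.end2),
            self.name, self.score, self.strand1, self.strand2,
            *self.extra,
        ]
        return "\t".join(cols)


@dataclass
class DomainTableRow:
    """One protein-domain annotation keyed by a transcript/protein accession."""

    protein_or_transcript_id: str
    domain_name: str
    start_aa: int  # 1-based inclusive
    end_aa: int    # 1-based inclusive


@dataclass
class IdeogramBand:
    """One cytogenetic (Giemsa) band, UCSC cytoBand column order."""

    chrom: str
    start: int
    end: int
    band_name: str
    stain: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(f"ideogram band {self.band_name}: start >= end")


@dataclass
class CountMatrix:
    """FeatureCounts-style gene-by-sample read counts with gene lengths."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: pd.DataFrame       # genes x samples, non-negative ints
    gene_lengths: pd.Series    # bp per gene, positive

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("count matrix contains negative counts")
        if (self.gene_lengths <= 0).any():
            bad = self.gene_lengths[self.gene_lengths <= 0].index.tolist()
            raise FormatError(f"non-positive gene length for {bad}")


def _parse_header_labels(line: str) -> list[str]:
    return [c.strip().lstrip("#") for c in line.rstrip("\n").split("\t")]


def read_bedpe(path: str | Path) -> list[BedpeRecord]:
    """Parse a BEDPE fusion-candidate file.

    Requires >= 10 tab-separated columns per data line.  A header comment
    whose trailing fields name ``spanning``/``encompassing``/``sample``
    columns makes those counts available on the records; otherwise
    supporting-read counts default to 0.
    """
    path = Path(path)
    records: list[BedpeRecord] = []
    extra_labels: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                labels = _parse_header_labels(line)
                if len(labels) > 10 and any(
                    k in lbl.lower() for lbl in labels[10:] for k in EXTRA_COLUMN_KEYS
                ):
                    extra_labels = labels[10:]
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise FormatError(
                    f"{path}:{lineno}: BEDPE needs >= 10 columns, got {len(cols)}"
                )
            try:
                coords = [int(c) for c in (cols[1], cols[2], cols[4], cols[5])]
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate: {exc}"
                ) from None
            rec = BedpeRecord(
                chrom1=cols[0], start1=coords[0], end1=coords[1],
                chrom2=cols[3], start2=coords[2], end2=coords[3],
                name=cols[6], score=cols[7], strand1=cols[8], strand2=cols[9],
                extra=cols[10:],
                extra_labels=extra_labels[: len(cols) - 10],
            )
            records.append(rec)
    return records


def write_bedpe(records: Iterable[BedpeRecord], path: str | Path) -> None:
    """Write records back to BEDPE, emitting a labelled header when present."""
    records = list(records)
    with open(path, "w") as fh:
        labels = records[0].extra_labels if records else []
        header = [
            "chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "name", "score", "strand1", "strand2", *labels,
        ]
        fh.write("#" + "\t".join(header) + "\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_domain_table(path: str | Path) -> list[DomainTableRow]:
    """Parse a TSV protein-domain table (id, name, start_aa, end_aa).

    Rows with end < start are skipped with a warning rather than aborting,
    since public domain dumps occasionally carry inverted rows.
    """
    path = Path(path)
    rows: list[DomainTableRow] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(
                    f"{path}:{lineno}: domain table needs >= 4 columns"
                )
            try:
                start_aa, end_aa = int(cols[2]), int(cols[3])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric amino-acid position"
                ) from None
            if not 1 <= start_aa <= end_aa:
                logger.warning(
                    "%s:%d: skipping domain row with start_aa > end_aa (%d > %d)",
                    path, lineno, start_aa, end_aa,
                )
                continue
            rows.append(DomainTableRow(cols[0], cols[1], start_aa, end_aa))
    return rows


def read_ideogram(path: str | Path) -> list[IdeogramBand]:
    """Parse a UCSC cytoBand-style TSV (chrom, start, end, name, gieStain)."""
    path = Path(path)
    bands: list[IdeogramBand] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise FormatError(f"{path}:{lineno}: ideogram needs 5 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer band coordinate"
                ) from None
            bands.append(IdeogramBand(cols[0], start, end, cols[3], cols[4]))
    return bands


def read_count_matrix(path: str | Path, length_column: str = "Length") -> CountMatrix:
    """Parse a FeatureCounts-style TSV: gene id, a length column, then samples.

    Raises :class:`FormatError` on duplicate gene ids, ragged rows or
    negative counts.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed TSV: {exc}") from None
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate gene ids {dups}")
    if length_column not in df.columns:
        raise FormatError(f"{path}: missing length column {length_column!r}")
    lengths = df[length_column].astype(int)
    counts = df.drop(columns=[length_column])
    if counts.isna().any().any():
        raise FormatError(f"{path}: ragged rows (missing values) in count matrix")
    counts = counts.astype(int)
    return CountMatrix(
        gene_ids=list(df.index),
        sample_ids=list(counts.columns),
        counts=counts,
        gene_lengths=lengths,
    )


def write_annotation_table(rows: list[dict], path: str | Path) -> None:
    """Write the annotated-fusion sidecar TSV, one row per fusion isoform pair.

    Columns: fusion name, 5'/3' transcript accessions, junction exons, frame
    status, and the retained domains as ``name:start-end(fraction)`` items.
    """
    columns = [
        "fusion", "tx5", "tx3", "junction_exon5", "junction_exon3",
        "frame_status", "junction_offset", "cdna_length", "retained_domains",
    ]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)
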