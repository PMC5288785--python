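"""Genomic coordinate types, annotation/alignment I/O, and interval counting.

All coordinates are 0-based half-open internally (BED convention); GTF input
(1-based, end-inclusive) is converted on read.  A 1-bp feature therefore has
``end == start + 1``.

Mark-specific counting regions follow the promoter/gene-body conventions:

* H3K4me3 — a symmetric window around the transcription start site,
  ``[tss - flank, tss + flank)``.
* H3K27me3 — the gene body extended by ``flank`` bp upstream of the TSS,
  i.e. ``[tss - flank, tts)`` on the + strand and ``[tts, tss + flank)``
  on the - strand.

Read BED files use the score column as a uniqueness indicator: score > 0
means the read mapped uniquely.  BAM input is out of scope; convert with
``bedtools bamtobed`` upstream.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "H3K4ME3",
    "H3K27ME3",
    "MARKS",
    "GenomicInterval",
    "GeneModel",
    "AlignedReadSet",
    "AnnotationError",
    "BedError",
    "RegionError",
    "read_gene_annotation",
    "read_alignments_bed",
    "write_reads_bed",
    "write_regions_bed",
    "write_genes_bed12",
    "write_genes_gtf",
    "mark_region",
    "count_overlaps",
]

H3K4ME3 = "H3K4me3"
H3K27ME3 = "H3K27me3"
MARKS = (H3K4ME3, H3K27ME3)

_STRANDS = ("+", "-", ".")


class AnnotationError(ValueError):
    """A gene-annotation stream could not be parsed into gene models."""


class BedError(ValueError):
    """A BED stream is malformed."""


class RegionError(ValueError):
    """A counting region collapsed to zero width after clipping."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp (half-open arithmetic)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """One gene: its locus, orientation, and the transcript length used as
    the FPKM denominator (summed exon length of the representative
    transcript)."""

    gene_id: str
    locus: GenomicInterval
    transcript_length: int

    def __post_init__(self) -> None:
        if self.locus.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: locus must be stranded (+/-)")
        if not (1 <= self.transcript_length <= self.locus.width):
            raise ValueError(
                f"gene {self.gene_id}: transcript_length {self.transcript_length} "
                f"outside [1, locus width {self.locus.width}]"
            )

    @property
    def tss(self) -> int:
        """Transcription start site: locus.start on +, locus.end on -."""
        return self.locus.start if self.locus.strand == "+" else self.locus.end

    @property
    def tts(self) -> int:
        """Transcription termination site (opposite end from the TSS)."""
        return self.locus.end if self.locus.strand == "+" else self.locus.start


class AlignedReadSet:
    """One sequencing library held as parallel coordinate arrays.

    ``total_mapped`` counts the retained (uniquely mapped) reads and is the
    RPM denominator downstream.
    """

    def __init__(
        self,
        library_id: str,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        unique: Sequence[bool] | None = None,
    ) -> None:
        self.library_id = library_id
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        if unique is None:
            unique = np.ones(self.starts.size, dtype=bool)
        self.unique = np.asarray(unique, dtype=bool)
        n = self.starts.size
        if not (self.chroms.size == n == self.ends.size == self.unique.size):
            raise ValueError("chroms/starts/ends/unique must have equal length")
        if n and (np.any(self.starts < 0) or np.any(self.starts >= self.ends)):
            raise ValueError("read intervals must satisfy 0 <= start < end")
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
        self._mid_index: dict[str, np.ndarray] | None = None

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def total_mapped(self) -> int:
        return int(self.unique.sum())

    @property
    def reads(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(str(c), int(s), int(e))
            for c, s, e in zip(self.chroms, self.starts, self.ends)
        ]

    @classmethod
    def from_intervals(
        cls,
        library_id: str,
        intervals: Iterable[GenomicInterval],
        unique: Sequence[bool] | None = None,
    ) -> "AlignedReadSet":
        ivs = list(intervals)
        return cls(
            library_id,
            [iv.chrom for iv in ivs],
            [iv.start for iv in ivs],
            [iv.end for iv in ivs],
            unique,
        )

    def filter_unique(self) -> "AlignedReadSet":
        """Drop multi-mapped reads; the result has all-true flags."""
        keep = self.unique
        return AlignedReadSet(
            self.library_id,
            self.chroms[keep],
            self.starts[keep],
            self.ends[keep],
        )

    # -- counting -----------------------------------------------------------

    def _chrom_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        # Sorted starts and (independently) sorted ends per chromosome over
        # unique reads only.  count(start < E) - count(end <= S) gives the
        # number of intervals overlapping [S, E).
        if self._index is None:
            index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            keep = self.unique
            chroms = self.chroms[keep]
            starts = self.starts[keep]
            ends = self.ends[keep]
            order = np.argsort(chroms, kind="stable")
            chroms = chroms[order]
            starts = starts[order]
            ends = ends[order]
            if chroms.size:
                bounds = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
                pieces = np.split(np.arange(chroms.size), bounds)
                for piece in pieces:
                    c = str(chroms[piece[0]])
                    index[c] = (np.sort(starts[piece]), np.sort(ends[piece]))
            self._index = index
        return self._index

    def midpoints(self, chrom: str) -> np.ndarray:
        """Sorted read midpoints on ``chrom`` (unique reads only)."""
        if self._mid_index is None:
            mids: dict[str, np.ndarray] = {}
            keep = self.unique
            chroms = self.chroms[keep]
            centers = (self.starts[keep] + self.ends[keep]) // 2
            order = np.argsort(chroms, kind="stable")
            chroms = chroms[order]
            centers = centers[order]
            if chroms.size:
                bounds = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
                for piece in np.split(np.arange(chroms.size), bounds):
                    mids[str(chroms[piece[0]])] = np.sort(centers[piece])
            self._mid_index = mids
        return self._mid_index.get(chrom, np.empty(0, dtype=np.int64))

    def count_overlaps(self, region: GenomicInterval) -> int:
        """Number of unique reads overlapping ``region`` by >= 1 bp."""
        idx = self._chrom_index().get(region.chrom)
        if idx is None:
            return 0
        starts, ends = idx
        lo = np.searchsorted(ends, region.start, side="right")
        hi = np.searchsorted(starts, region.end, side="left")
        return int(hi - lo)

    def count_overlaps_many(self, regions: Sequence[GenomicInterval]) -> np.ndarray:
        """Vectorised :meth:`count_overlaps` over many regions."""
        out = np.zeros(len(regions), dtype=np.int64)
        index = self._chrom_index()
        for i, region in enumerate(regions):
            idx = index.get(region.chrom)
            if idx is None:
                continue
            starts, ends = idx
            out[i] = np.searchsorted(starts, region.end, side="left") - np.searchsorted(
                ends, region.start, side="right"
            )
        return out


def count_overlaps(reads: AlignedReadSet, region: GenomicInterval) -> int:
    """Count unique reads in ``reads`` overlapping ``region`` by >= 1 bp.

    Half-open arithmetic: a read abutting the region boundary does not count.
    Strand is ignored; chromosomes must match.
    """
    return reads.count_overlaps(region)


def mark_region(
    gene: GeneModel,
    mark: str,
    flank: int = 2000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> GenomicInterval:
    """Counting region for a histone mark at ``gene``.

    H3K4me3: ``[tss - flank, tss + flank)``.  H3K27me3: gene body plus the
    upstream flank.  The region is clipped at 0 and, when ``chrom_sizes`` is
    given, at the chromosome end; clipping that empties the region raises
    :class:`RegionError`.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    if mark == H3K4ME3:
        start, end = gene.tss - flank, gene.tss + flank
    elif mark == H3K27ME3:
        if gene.locus.strand == "+":
            start, end = gene.tss - flank, gene.tts
        else:
            start, end = gene.tts, gene.tss + flank
    else:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    chrom = gene.locus.chrom
    start = max(start, 0)
    if chrom_sizes is not None and chrom in chrom_sizes:
        end = min(end, chrom_sizes[chrom])
    if start >= end:
        raise RegionError(
            f"gene {gene.gene_id}: {mark} region empty after clipping "
            f"([{start}, {end}) on {chrom})"
        )
    return GenomicInterval(chrom, start, end, gene.locus.strand)


# ---------------------------------------------------------------------------
# annotation I/O


def _as_lines(source) -> list[str]:
    if isinstance(source, (str, os.PathLike)):
        with open(source, "rt") as fh:
            return fh.read().splitlines()
    if isinstance(source, io.TextIOBase) or hasattr(source, "read"):
        return source.read().splitlines()
    raise TypeError(f"cannot read annotation from {type(source)!r}")


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gene_annotation(source, fmt: str | None = None) -> list[GeneModel]:
    """Parse a GTF (Ensembl dialect) or BED (6 or 12 column) annotation.

    One :class:`GeneModel` is produced per ``gene_id``; for GTF input with
    several transcripts, the transcript with the largest summed exon length
    is the representative (ties broken by transcript_id).  Genes without
    exons are rejected.  The format is sniffed from the first data line
    unless ``fmt`` (``"gtf"``/``"bed"``) is given.
    """
    lines = _as_lines(source)
    data = [
        (i + 1, ln)
        for i, ln in enumerate(lines)
        if ln.strip() and not ln.startswith(("#", "track", "browser"))
    ]
    if not data:
        return []
    if fmt is None:
        fields = data[0][1].rstrip("\n").split("\t")
        if len(fields) >= 9 and "gene_id" in fields[8]:
            fmt = "gtf"
        elif len(fields) >= 4:
            fmt = "bed"
        else:
            raise AnnotationError(
                f"line {data[0][0]}: cannot identify annotation format "
                f"({len(fields)} tab-separated fields)"
            )
    if fmt == "gtf":
        return _parse_gtf(data)
    if fmt == "bed":
        return _parse_bed_annotation(data)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _parse_gtf(data: list[tuple[int, str]]) -> list[GeneModel]:
    # transcript_id -> [gene_id, chrom, strand, [(start0, end0), ...]]
    transcripts: dict[str, list] = {}
    gene_order: list[str] = []
    seen_genes: set[str] = set()
    for lineno, line in data:
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise AnnotationError(
                f"line {lineno}: expected 9 tab-separated GTF fields, got {len(fields)}"
            )
        chrom, _, feature, start, end, _, strand, _, attrs = fields
        try:
            start1, end1 = int(start), int(end)
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: non-integer coordinates") from exc
        if start1 < 1 or end1 < start1:
            raise AnnotationError(f"line {lineno}: invalid GTF coordinates {start}-{end}")
        attr = dict(_GTF_ATTR.findall(attrs))
        gene_id = attr.get("gene_id")
        if gene_id is None:
            raise AnnotationError(f"line {lineno}: missing gene_id attribute")
        if gene_id not in seen_genes:
            seen_genes.add(gene_id)
            gene_order.append(gene_id)
        if feature != "exon":
            continue
        tid = attr.get("transcript_id")
        if tid is None:
            raise AnnotationError(f"line {lineno}: exon without transcript_id")
        if strand not in ("+", "-"):
            raise AnnotationError(f"line {lineno}: exon needs +/- strand, got {strand!r}")
        rec = transcripts.setdefault(tid, [gene_id, chrom, strand, []])
        rec[3].append((start1 - 1, end1))

    by_gene: dict[str, list[tuple[str, str, str, list]]] = {}
    for tid, (gene_id, chrom, strand, exons) in transcripts.items():
        by_gene.setdefault(gene_id, []).append((tid, chrom, strand, exons))

    genes: list[GeneModel] = []
    for gene_id in gene_order:
        if gene_id not in by_gene:
            raise AnnotationError(f"gene {gene_id}: no exon features")
        # representative = longest transcript (summed exon length)
        best = max(
            by_gene[gene_id],
            key=lambda t: (sum(e - s for s, e in t[3]), t[0]),
        )
        tid, chrom, strand, exons = best
        length = sum(e - s for s, e in exons)
        start = min(s for s, _ in exons)
        end = max(e for _, e in exons)
        try:
            genes.append(
                GeneModel(gene_id, GenomicInterval(chrom, start, end, strand), length)
            )
        except ValueError as exc:
            raise AnnotationError(f"gene {gene_id}: {exc}") from exc
    return genes


def _parse_bed_annotation(data: list[tuple[int, str]]) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for lineno, line in data:
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 6:
            raise AnnotationError(
                f"line {lineno}: BED annotation needs >= 6 fields, got {len(fields)}"
            )
        chrom, start, end, name, _, strand = fields[:6]
        try:
            start0, end0 = int(start), int(end)
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: non-integer coordinates") from exc
        if start0 < 0 or end0 <= start0:
            raise AnnotationError(f"line {lineno}: invalid interval [{start}, {end})")
        if strand not in ("+", "-"):
            raise AnnotationError(f"line {lineno}: gene needs +/- strand, got {strand!r}")
        if len(fields) >= 12:
            try:
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: malformed BED12 blocks") from exc
            if len(sizes) != block_count:
                raise AnnotationError(
                    f"line {lineno}: blockCount {block_count} != {len(sizes)} blockSizes"
                )
            if block_count == 0:
                raise AnnotationError(f"gene {name}: zero exon blocks (line {lineno})")
            length = sum(sizes)
        else:
            length = end0 - start0
        try:
            genes.append(
                GeneModel(name, GenomicInterval(chrom, start0, end0, strand), length)
            )
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: {exc}") from exc
    return genes


# ---------------------------------------------------------------------------
# read I/O (BED6 dialect: score > 0 marks a uniquely mapped read)


def read_alignments_bed(
    source,
    unique_only: bool = False,
    library_id: str | None = None,
) -> AlignedReadSet:
    """Read aligned read intervals from BED (>= 3 columns).

    Column 5 (score), when present, is the uniqueness indicator: score > 0
    means uniquely mapped.  Without a score column every read is treated as
    unique.  With ``unique_only`` non-unique reads are dropped so that
    ``total_mapped`` equals the retained count.
    """
    if library_id is None:
        library_id = str(source) if isinstance(source, (str, os.PathLike)) else "reads"
    try:
        df = pd.read_csv(
            source, sep="\t", header=None, comment="#", dtype={0: str}
        )
    except pd.errors.EmptyDataError:
        return AlignedReadSet(library_id, [], [], [], [])
    if df.shape[1] < 3:
        raise BedError(f"{library_id}: BED needs >= 3 columns, got {df.shape[1]}")
    chroms = df[0].astype(str).to_numpy(dtype=object)
    starts = pd.to_numeric(df[1], errors="coerce")
    ends = pd.to_numeric(df[2], errors="coerce")
    bad = starts.isna() | ends.isna()
    if bad.any():
        raise BedError(f"{library_id}: non-numeric coordinates at line {bad.idxmax() + 1}")
    starts = starts.to_numpy(dtype=np.int64)
    ends = ends.to_numpy(dtype=np.int64)
    invalid = (starts < 0) | (starts >= ends)
    if invalid.any():
        lineno = int(np.flatnonzero(invalid)[0]) + 1
        raise BedError(
            f"{library_id}: line {lineno}: invalid interval "
            f"[{starts[lineno - 1]}, {ends[lineno - 1]})"
        )
    if df.shape[1] >= 5:
        score = pd.to_numeric(df[4], errors="coerce").fillna(0).to_numpy()
        unique = score > 0
    else:
        unique = np.ones(starts.size, dtype=bool)
    rs = AlignedReadSet(library_id, chroms, starts, ends, unique)
    return rs.filter_unique() if unique_only else rs


def write_reads_bed(reads: AlignedReadSet, path) -> None:
    """Write reads as BED6 (name = ordinal, score = uniqueness flag)."""
    with open(path, "wt") as fh:
        for i in range(len(reads)):
            fh.write(
                f"{reads.chroms[i]}\t{reads.starts[i]}\t{reads.ends[i]}"
                f"\tr{i}\t{1 if reads.unique[i] else 0}\t.\n"
            )


def write_regions_bed(regions: Iterable[tuple[str, GenomicInterval]], path) -> None:
    """Write named regions as BED6."""
    with open(path, "wt") as fh:
        for name, region in regions:
            fh.write(
                f"{region.chrom}\t{region.start}\t{region.end}\t{name}\t0\t{region.strand}\n"
            )


def write_genes_bed12(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as single-block BED12 records."""
    with open(path, "wt") as fh:
        for g in genes:
            loc = g.locus
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{g.gene_id}\t0\t{loc.strand}"
                f"\t{loc.start}\t{loc.end}\t0\t1\t{loc.width},\t0,\n"
            )


def write_genes_gtf(genes: Sequence[GeneModel], path, source: str = "markgene") -> None:
    """Write gene models as GTF gene/transcript/exon triplets (1-based)."""
    with open(path, "wt") as fh:
        for g in genes:
            loc = g.locus
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            for feature in ("gene", "transcript", "exon"):
                fh.write(
                    f"{loc.chrom}\t{source}\t{feature}\t{loc.start + 1}\t{loc.end}"
                    f"\t.\t{loc.strand}\t.\t{attrs}\n"
                )
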