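"""Per-gene histone-mark enrichment (RPM-normalised ChIP/input ratio) and
metagene read-density profiles.

Enrichment per gene is ``chip_rpm / input_rpm`` where each RPM is
``1e6 * (count + pseudocount) / total_mapped`` counted over the mark's
region (promoter window for H3K4me3, upstream-flank + gene body for
H3K27me3).  The symmetric 0.5-read pseudocount keeps ratios finite at
zero-count genes.

Profiles assign read midpoints to bins; densities are reads-per-million
per bp per gene, so libraries of different depth are directly comparable.
No input subtraction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import (
    H3K27ME3,
    H3K4ME3,
    MARKS,
    AlignedReadSet,
    GeneModel,
    mark_region,
)

__all__ = [
    "rpm",
    "enrichment",
    "EnrichmentRecord",
    "gene_enrichment_table",
    "enrichment_fold_change",
    "enrichment_fold_change_table",
    "MetageneProfile",
    "metagene_profile",
]

logger = logging.getLogger(__name__)


def rpm(count, total_mapped: int, pseudocount: float = 0.5):
    """Reads per million: ``1e6 * (count + pseudocount) / total_mapped``."""
    if total_mapped < 1:
        raise ValueError(f"total_mapped must be >= 1, got {total_mapped}")
    counts = np.asarray(count, dtype=float)
    if np.any(counts < 0):
        raise ValueError("count must be non-negative")
    out = 1e6 * (counts + pseudocount) / float(total_mapped)
    return float(out) if out.ndim == 0 else out


def enrichment(chip_rpm, input_rpm):
    """ChIP/input RPM ratio; the input RPM must be positive."""
    chip = np.asarray(chip_rpm, dtype=float)
    inp = np.asarray(input_rpm, dtype=float)
    if np.any(inp <= 0):
        raise ValueError("input_rpm must be > 0 (apply a pseudocount upstream)")
    out = chip / inp
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EnrichmentRecord:
    """One gene x mark x genotype enrichment measurement."""

    gene_id: str
    mark: str
    genotype: str
    chip_count: int
    input_count: int
    chip_rpm: float
    input_rpm: float
    enrichment: float


def gene_enrichment_table(
    genes: Sequence[GeneModel],
    chip: AlignedReadSet,
    input_: AlignedReadSet,
    mark: str,
    genotype: str,
    flank: int = 2000,
    pseudocount: float = 0.5,
    chrom_sizes=None,
) -> pd.DataFrame:
    """Per-gene enrichment table for one mark and genotype.

    Columns: mark, genotype, chip_count, input_count, chip_rpm, input_rpm,
    enrichment; indexed by gene_id.  Both libraries are filtered to unique
    reads before counting; a zero-total library is an error.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}")
    chip = chip.filter_unique()
    input_ = input_.filter_unique()
    if genes and (chip.total_mapped == 0 or input_.total_mapped == 0):
        raise ValueError("cannot score enrichment against an empty library")
    regions = [mark_region(g, mark, flank=flank, chrom_sizes=chrom_sizes) for g in genes]
    chip_counts = chip.count_overlaps_many(regions)
    input_counts = input_.count_overlaps_many(regions)
    chip_r = rpm(chip_counts, chip.total_mapped, pseudocount) if genes else np.array([])
    input_r = rpm(input_counts, input_.total_mapped, pseudocount) if genes else np.array([])
    df = pd.DataFrame(
        {
            "mark": mark,
            "genotype": genotype,
            "chip_count": chip_counts,
            "input_count": input_counts,
            "chip_rpm": chip_r,
            "input_rpm": input_r,
            "enrichment": enrichment(chip_r, input_r) if genes else np.array([]),
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    return df


def records(table: pd.DataFrame):
    """Yield :class:`EnrichmentRecord` objects from an enrichment table."""
    for gene_id, row in table.iterrows():
        yield EnrichmentRecord(
            gene_id=str(gene_id),
            mark=row["mark"],
            genotype=row["genotype"],
            chip_count=int(row["chip_count"]),
            input_count=int(row["input_count"]),
            chip_rpm=float(row["chip_rpm"]),
            input_rpm=float(row["input_rpm"]),
            enrichment=float(row["enrichment"]),
        )


def enrichment_fold_change(record_test: EnrichmentRecord, record_ref: EnrichmentRecord) -> float:
    """Ratio of enrichment between two genotypes for the same gene and mark."""
    if record_test.gene_id != record_ref.gene_id:
        raise ValueError(
            f"gene mismatch: {record_test.gene_id} vs {record_ref.gene_id}"
        )
    if record_test.mark != record_ref.mark:
        raise ValueError(f"mark mismatch: {record_test.mark} vs {record_ref.mark}")
    return record_test.enrichment / record_ref.enrichment


def enrichment_fold_change_table(
    table_test: pd.DataFrame, table_ref: pd.DataFrame
) -> pd.Series:
    """Per-gene enrichment fold change (test/ref) for aligned tables."""
    if not table_test.index.equals(table_ref.index):
        raise ValueError("enrichment tables cover different gene sets")
    marks_t = set(table_test["mark"].unique())
    marks_r = set(table_ref["mark"].unique())
    if marks_t != marks_r:
        raise ValueError(f"mark mismatch between tables: {marks_t} vs {marks_r}")
    out = table_test["enrichment"] / table_ref["enrichment"]
    out.name = "enrichment_fc"
    return out


@dataclass(frozen=True)
class MetageneProfile:
    """Binned read density averaged over genes.

    ``density`` is reads-per-million per bp per gene.  For ``tss_centered``
    profiles ``bin_edges`` are bp offsets from the TSS; for ``scaled_body``
    they are in flank-relative units (upstream [-1, 0), body [0, 1) as gene
    fractions, downstream [1, 2)).
    """

    mode: str
    bin_edges: np.ndarray
    density: np.ndarray
    n_genes: int
    window: int
    total_mapped: int

    @property
    def assigned_reads(self) -> float:
        """Read-gene assignments implied by the density (tss mode only)."""
        if self.mode != "tss_centered":
            raise ValueError("assigned_reads defined for tss_centered profiles only")
        widths = np.diff(self.bin_edges)
        return float(
            np.sum(self.density * widths) * self.n_genes * self.total_mapped / 1e6
        )


def metagene_profile(
    reads: AlignedReadSet,
    genes: Sequence[GeneModel],
    mode: str = "tss_centered",
    window: int = 2000,
    n_bins: int = 100,
    flank_bins: int | None = None,
) -> MetageneProfile:
    """Average read-midpoint density over genes on a common frame.

    ``tss_centered``: per-gene windows ``[tss - window, tss + window)``
    split into ``n_bins`` equal bins, orientation flipped for - strand
    genes.  ``scaled_body``: the gene body is mapped to ``n_bins`` equal
    fractions with fixed-width flanks of ``window`` bp split into
    ``flank_bins`` bins each (default ``max(1, n_bins // 5)``).
    """
    if not genes:
        raise ValueError("metagene profile needs at least one gene")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if mode not in ("tss_centered", "scaled_body"):
        raise ValueError(f"unknown profile mode {mode!r}")
    reads = reads.filter_unique()
    total = reads.total_mapped
    if total == 0:
        raise ValueError("cannot profile an empty library")
    n_genes = len(genes)

    if mode == "tss_centered":
        edges = np.linspace(-window, window, n_bins + 1)
        width = 2.0 * window / n_bins
        counts = np.zeros(n_bins)
        for gene in genes:
            mids = reads.midpoints(gene.locus.chrom)
            lo = np.searchsorted(mids, gene.tss - window, side="left")
            hi = np.searchsorted(mids, gene.tss + window, side="right")
            m = mids[lo:hi]
            offset = m - gene.tss if gene.locus.strand == "+" else gene.tss - m
            sel = (offset >= -window) & (offset < window)
            idx = np.floor((offset[sel] + window) / width).astype(np.int64)
            np.clip(idx, 0, n_bins - 1, out=idx)
            counts += np.bincount(idx, minlength=n_bins)
        density = counts / (width * n_genes * total / 1e6)
        return MetageneProfile(mode, edges, density, n_genes, window, total)

    # scaled_body
    if flank_bins is None:
        flank_bins = max(1, n_bins // 5)
    fw = window / flank_bins
    up = np.zeros(flank_bins)
    body = np.zeros(n_bins)
    down = np.zeros(flank_bins)
    for gene in genes:
        mids = reads.midpoints(gene.locus.chrom)
        body_len = abs(gene.tts - gene.tss)
        lo_coord = min(gene.tss, gene.tts) - window
        hi_coord = max(gene.tss, gene.tts) + window
        m = mids[np.searchsorted(mids, lo_coord) : np.searchsorted(mids, hi_coord)]
        # oriented offset from the TSS, positive into the gene body
        offset = m - gene.tss if gene.locus.strand == "+" else gene.tss - m
        in_up = (offset >= -window) & (offset < 0)
        in_body = (offset >= 0) & (offset < body_len)
        in_down = (offset >= body_len) & (offset < body_len + window)
        if in_up.any():
            idx = np.floor((offset[in_up] + window) / fw).astype(np.int64)
            np.clip(idx, 0, flank_bins - 1, out=idx)
            up += np.bincount(idx, minlength=flank_bins) / fw
        if in_body.any():
            bw = body_len / n_bins
            idx = np.floor(offset[in_body] / bw).astype(np.int64)
            np.clip(idx, 0, n_bins - 1, out=idx)
            body += np.bincount(idx, minlength=n_bins) / bw
        if in_down.any():
            idx = np.floor((offset[in_down] - body_len) / fw).astype(np.int64)
            np.clip(idx, 0, flank_bins - 1, out=idx)
            down += np.bincount(idx, minlength=flank_bins) / fw
    density = np.concatenate([up, body, down]) / (n_genes * total / 1e6)
    edges = np.concatenate(
        [
            np.linspace(-1.0, 0.0, flank_bins + 1)[:-1],
            np.linspace(0.0, 1.0, n_bins + 1)[:-1],
            np.linspace(1.0, 2.0, flank_bins + 1),
        ]
    )
    return MetageneProfile(mode, edges, density, n_genes, window, total)


def profile_frame(profile: MetageneProfile) -> pd.DataFrame:
    """Tabular form of a profile (bin_start, bin_end, density)."""
    return pd.DataFrame(
        {
            "bin_start": profile.bin_edges[:-1],
            "bin_end": profile.bin_edges[1:],
            "density": profile.density,
        }
    )
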