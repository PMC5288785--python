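"""Synthetic two-genotype study generator.

Produces non-overlapping gene models, negative-binomial expression counts
with planted up/down genes, and ChIP/input read libraries in which per-gene
ChIP/input enrichment ratios are planted and coupled to the expression
classes (down-regulated genes lose H3K4me3 and gain H3K27me3 in the test
genotype, and vice versa for up-regulated genes).

Read placement uses a two-component mixture: a uniform genomic background
plus gene-assigned reads positioned Normal(TSS, k4_sigma) for H3K4me3 or
uniformly over the gene body for H3K27me3.  The background weight is solved
so that the *expected* RPM-ratio enrichment of every gene equals its
requested ratio exactly (possible whenever sum(ratio * region) <= genome
size); setting ``background_fraction`` above the solved weight falls back to
literal mixture semantics (``background_fraction=1`` gives an input-like
library).  Matching input libraries are uniform over the genome.

All randomness flows from a single integer seed; outputs are byte-stable
across runs with the same configuration.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .expression import DOWN, UNCHANGED, UP
from .genome import (
    H3K27ME3,
    H3K4ME3,
    MARKS,
    AlignedReadSet,
    GeneModel,
    GenomicInterval,
    mark_region,
    write_genes_bed12,
    write_genes_gtf,
    write_reads_bed,
)

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_genes",
    "simulate_expression",
    "simulate_chip_library",
    "simulate_input_library",
    "simulate_study",
]

CHIP = "chip"
INPUT = "input"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic study; defaults run in seconds."""

    n_genes: int = 200
    chrom_length: int = 3_000_000
    n_chroms: int = 2
    de_fraction: float = 0.2
    expr_log2fc_effect: float = 2.0
    count_dispersion: float = 0.05
    reads_per_chip_library: int = 100_000
    reads_per_input_library: int = 100_000
    read_length: int = 50
    k4_sigma: float = 500.0
    k4_coupling: float = 1.0
    k27_coupling: float = 1.0
    background_fraction: float = 0.0
    seed: int = 0
    # secondary knobs (not part of the core design grid)
    n_replicates: int = 1
    k4_base_enrichment: float = 4.0
    k27_base_enrichment: float = 2.0
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    gene_min_length: int = 1_000
    gene_max_length: int = 20_000
    gene_spacing: int = 4_000
    flank: int = 2_000
    genotype_ref: str = "XY"
    genotype_test: str = "XXSry"

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background_fraction must be in [0, 1]")
        if self.k4_sigma <= 0:
            raise ValueError("k4_sigma must be > 0")
        for name in (
            "n_genes",
            "chrom_length",
            "n_chroms",
            "reads_per_chip_library",
            "reads_per_input_library",
            "read_length",
            "n_replicates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be > 0")
        if self.gene_min_length < 1 or self.gene_max_length < self.gene_min_length:
            raise ValueError("invalid gene length range")

    @property
    def genome_length(self) -> int:
        return self.n_chroms * self.chrom_length

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}


@dataclass(frozen=True)
class SimulatedStudy:
    """A complete in-memory synthetic study plus its ground truth.

    ``truth`` has one row per gene: de_class, expr_log2fc, and the planted /
    expected enrichment per mark and genotype.  ``libraries`` maps
    (mark, fraction, genotype) to an :class:`AlignedReadSet`.
    """

    config: SimulationConfig
    genes: list[GeneModel]
    counts: pd.DataFrame
    sample_genotypes: dict[str, str]
    libraries: dict[tuple[str, str, str], AlignedReadSet]
    truth: pd.DataFrame


def _spawn(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=keys))


def simulate_genes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Non-overlapping single-exon genes with log-uniform lengths.

    Genes are spaced >= ``gene_spacing`` bp apart (default 4 kb, so +/-2 kb
    promoter windows of neighbours never overlap) and kept clear of
    chromosome ends.
    """
    if rng is None:
        rng = _spawn(config.seed, 0)
    n = config.n_genes
    lengths = np.exp(
        rng.uniform(np.log(config.gene_min_length), np.log(config.gene_max_length), n)
    ).astype(np.int64)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    per_chrom = np.full(config.n_chroms, n // config.n_chroms, dtype=int)
    per_chrom[: n % config.n_chroms] += 1
    genes: list[GeneModel] = []
    i = 0
    for chrom, k in zip(config.chrom_names, per_chrom):
        if k == 0:
            continue
        chrom_lengths = lengths[i : i + k]
        required = int(chrom_lengths.sum() + (k + 1) * config.gene_spacing)
        slack = config.chrom_length - required
        if slack < 0:
            need = config.n_chroms * required
            raise ValueError(
                f"genome too small for {n} genes: need >= {need} bp total "
                f"({required} bp on {chrom}), have {config.genome_length}"
            )
        # distribute the slack over the k+1 inter-gene gaps
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        extra = np.diff(np.concatenate([[0], cuts, [slack]]))
        pos = 0
        for j in range(k):
            pos += config.gene_spacing + int(extra[j])
            start = pos
            end = start + int(chrom_lengths[j])
            genes.append(
                GeneModel(
                    gene_id=f"g{i + j:04d}",
                    locus=GenomicInterval(chrom, start, end, str(strands[i + j])),
                    transcript_length=int(chrom_lengths[j]),
                )
            )
            pos = end
        i += k
    return genes


def simulate_expression(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Negative-binomial counts for two genotypes with planted DE genes.

    Baseline per-gene means are log-normal; for planted genes the test
    genotype's mean is scaled by ``2**(+/-expr_log2fc_effect)`` (half up,
    half down).  Returns (counts, sample->genotype map, truth frame with
    de_class and expr_log2fc).
    """
    if rng is None:
        rng = _spawn(config.seed, 1)
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]
    n_de = int(round(config.de_fraction * n))
    if config.expr_log2fc_effect != 0 and n_de < 2:
        raise ValueError("de_fraction * n_genes must be >= 2 to plant up and down genes")
    mu = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    planted_log2fc = np.zeros(n)
    de_class = np.full(n, UNCHANGED, dtype=object)
    if config.expr_log2fc_effect != 0 and n_de >= 2:
        de_idx = rng.choice(n, size=n_de, replace=False)
        up_idx = de_idx[: n_de // 2]
        down_idx = de_idx[n_de // 2 :]
        planted_log2fc[up_idx] = config.expr_log2fc_effect
        planted_log2fc[down_idx] = -config.expr_log2fc_effect
        de_class[up_idx] = UP
        de_class[down_idx] = DOWN

    phi = config.count_dispersion  # var = mu + phi * mu^2
    counts = {}
    sample_genotypes: dict[str, str] = {}
    for genotype, shift in (
        (config.genotype_ref, np.zeros(n)),
        (config.genotype_test, planted_log2fc),
    ):
        mean = mu * 2.0**shift
        for rep in range(config.n_replicates):
            sample = f"{genotype}_rep{rep + 1}"
            lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
            counts[sample] = rng.poisson(lam).astype(np.int64)
            sample_genotypes[sample] = genotype
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.DataFrame(
        {"de_class": de_class, "expr_log2fc": planted_log2fc},
        index=counts_df.index,
    )
    return counts_df, sample_genotypes, truth


def _region_lengths(config: SimulationConfig, genes: Sequence[GeneModel], mark: str):
    regions = [
        mark_region(g, mark, flank=config.flank, chrom_sizes=config.chrom_sizes)
        for g in genes
    ]
    return regions, np.array([r.width for r in regions], dtype=float)


def _mixture_weights(
    config: SimulationConfig,
    region_lengths: np.ndarray,
    ratios: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Background weight u and per-gene assignment probabilities pi.

    Solves u so E[enrichment_g] = ratios_g exactly when feasible; otherwise
    (background_fraction above the solved value) uses the literal mixture
    with weights proportional to region * ratio.  Returns (u, pi,
    expected_enrichment).

    Expectations use effective widths (region + read_length - 1), since a
    read overlaps a region by >= 1 bp iff its start lies in that widened
    window; this is what the downstream any-overlap counter measures.
    """
    # uniform starts are drawn from chrom_length - read_length + 1 positions
    G = float(config.n_chroms * (config.chrom_length - config.read_length + 1))
    L = region_lengths + config.read_length - 1.0
    frac = L / G
    signal = float(np.sum(ratios * frac))
    if np.sum(frac) >= 1:
        raise ValueError("gene regions cover the whole genome; enlarge chrom_length")
    u0 = (1.0 - signal) / (1.0 - float(np.sum(frac)))
    if u0 < 0:
        need = int(np.ceil(np.sum(ratios * L)))
        raise ValueError(
            f"genome too small for requested enrichment ratios: need genome "
            f">= {need} bp, have {int(G)}"
        )
    if config.background_fraction <= u0:
        u = u0
        pi = np.clip(ratios - u, 0.0, None) * frac
        # feasible by construction: u + sum(pi) == 1 up to float error
        pi *= (1.0 - u) / pi.sum() if pi.sum() > 0 else 1.0
    else:
        u = config.background_fraction
        w = ratios * L
        if np.all(w == 0):
            raise ValueError("all-zero gene weights")
        pi = (1.0 - u) * w / w.sum()
    expected = u + pi / frac
    return u, pi, expected


def _uniform_positions(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform read start positions over the genome: (chrom_idx, start)."""
    chrom_idx = rng.integers(0, config.n_chroms, size=n)
    span = config.chrom_length - config.read_length
    starts = rng.integers(0, span + 1, size=n)
    return chrom_idx, starts


def simulate_chip_library(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    mark: str,
    genotype: str,
    ratios: np.ndarray,
    rng: np.random.Generator | None = None,
    library_id: str | None = None,
) -> tuple[AlignedReadSet, np.ndarray]:
    """One ChIP library with planted per-gene enrichment ratios.

    H3K4me3 reads centre Normal(TSS, k4_sigma); H3K27me3 reads are uniform
    over the gene body.  Returns the library and the per-gene *expected*
    enrichment implied by the realised mixture (equal to ``ratios`` in the
    calibrated regime).
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}")
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (len(genes),):
        raise ValueError("ratios must align with genes")
    if np.any(ratios <= 0):
        raise ValueError("planted ratios must be > 0")
    if rng is None:
        rng = _spawn(config.seed, 2, MARKS.index(mark), 0)
    if library_id is None:
        library_id = f"{mark}_{CHIP}_{genotype}"

    _, region_len = _region_lengths(config, genes, mark)
    u, pi, expected = _mixture_weights(config, region_len, ratios)
    n_reads = config.reads_per_chip_library
    probs = np.concatenate([[u], pi])
    probs = probs / probs.sum()
    component = rng.choice(len(probs), size=n_reads, p=probs)

    chrom_of = {c: i for i, c in enumerate(config.chrom_names)}
    chrom_idx = np.zeros(n_reads, dtype=np.int64)
    starts = np.zeros(n_reads, dtype=np.int64)

    bg = component == 0
    n_bg = int(bg.sum())
    if n_bg:
        chrom_idx[bg], starts[bg] = _uniform_positions(config, n_bg, rng)

    half = config.read_length // 2
    for gi, gene in enumerate(genes):
        sel = component == gi + 1
        k = int(sel.sum())
        if not k:
            continue
        if mark == H3K4ME3:
            mid = np.rint(rng.normal(gene.tss, config.k4_sigma, size=k)).astype(np.int64)
        else:
            body_lo = min(gene.tss, gene.tts)
            body_hi = max(gene.tss, gene.tts)
            mid = rng.integers(body_lo, body_hi, size=k)
        start = mid - half
        np.clip(start, 0, config.chrom_length - config.read_length, out=start)
        chrom_idx[sel] = chrom_of[gene.locus.chrom]
        starts[sel] = start

    chrom_names = np.array(config.chrom_names, dtype=object)
    reads = AlignedReadSet(
        library_id,
        chrom_names[chrom_idx],
        starts,
        starts + config.read_length,
    )
    return reads, expected


def simulate_input_library(
    config: SimulationConfig,
    genotype: str,
    mark: str,
    rng: np.random.Generator | None = None,
) -> AlignedReadSet:
    """A uniform-coverage control library."""
    if rng is None:
        rng = _spawn(config.seed, 2, MARKS.index(mark), 1)
    n = config.reads_per_input_library
    chrom_idx, starts = _uniform_positions(config, n, rng)
    chrom_names = np.array(config.chrom_names, dtype=object)
    return AlignedReadSet(
        f"{mark}_{INPUT}_{genotype}",
        chrom_names[chrom_idx],
        starts,
        starts + config.read_length,
    )


def _planted_ratios(
    config: SimulationConfig, truth: pd.DataFrame
) -> dict[tuple[str, str], np.ndarray]:
    """Requested per-gene enrichment ratios per (mark, genotype).

    The reference genotype carries base ratios.  In the test genotype, down
    genes have K4 scaled by 2**-k4_coupling and K27 by 2**+k27_coupling;
    reversed for up genes.
    """
    n = len(truth)
    de = truth["de_class"].to_numpy()
    sign = np.where(de == UP, 1.0, np.where(de == DOWN, -1.0, 0.0))
    out: dict[tuple[str, str], np.ndarray] = {}
    out[(H3K4ME3, config.genotype_ref)] = np.full(n, config.k4_base_enrichment)
    out[(H3K27ME3, config.genotype_ref)] = np.full(n, config.k27_base_enrichment)
    out[(H3K4ME3, config.genotype_test)] = config.k4_base_enrichment * 2.0 ** (
        sign * config.k4_coupling
    )
    out[(H3K27ME3, config.genotype_test)] = config.k27_base_enrichment * 2.0 ** (
        -sign * config.k27_coupling
    )
    return out


def simulate_study(
    config: SimulationConfig, outdir: str | os.PathLike | None = None
) -> SimulatedStudy:
    """Compose genes, expression, and the eight read libraries.

    When ``outdir`` is given, writes pipeline-ready inputs there: genes as
    BED12 and GTF, reads as BED6 per library, counts and truth as TSV, a
    sample sheet, and a ``config.yaml`` ready for the end-to-end runner.
    """
    genes = simulate_genes(config)
    counts, sample_genotypes, truth = simulate_expression(config, genes)
    ratios = _planted_ratios(config, truth)

    libraries: dict[tuple[str, str, str], AlignedReadSet] = {}
    truth = truth.copy()
    for mi, mark in enumerate(MARKS):
        for gi, genotype in enumerate((config.genotype_ref, config.genotype_test)):
            chip_rng = _spawn(config.seed, 2, mi, gi, 0)
            input_rng = _spawn(config.seed, 2, mi, gi, 1)
            chip, expected = simulate_chip_library(
                config, genes, mark, genotype, ratios[(mark, genotype)], rng=chip_rng
            )
            libraries[(mark, CHIP, genotype)] = chip
            libraries[(mark, INPUT, genotype)] = simulate_input_library(
                config, genotype, mark, rng=input_rng
            )
            key = "k4" if mark == H3K4ME3 else "k27"
            truth[f"{key}_ratio_{genotype}"] = ratios[(mark, genotype)]
            truth[f"{key}_expected_enrichment_{genotype}"] = expected

    study = SimulatedStudy(
        config=config,
        genes=genes,
        counts=counts,
        sample_genotypes=sample_genotypes,
        libraries=libraries,
        truth=truth,
    )
    if outdir is not None:
        write_study(study, outdir)
    return study


def write_study(study: SimulatedStudy, outdir: str | os.PathLike) -> dict[str, str]:
    """Write all study artifacts in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = study.config

    write_genes_bed12(study.genes, outdir / "genes.bed12")
    write_genes_gtf(study.genes, outdir / "genes.gtf")

    counts = study.counts.copy()
    counts.insert(0, "length", [g.transcript_length for g in study.genes])
    counts.to_csv(outdir / "counts.tsv", sep="\t")

    pd.DataFrame(
        {
            "sample_id": list(study.sample_genotypes),
            "genotype": list(study.sample_genotypes.values()),
        }
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)

    study.truth.to_csv(outdir / "truth.tsv", sep="\t", float_format="%.10g")

    pipeline_config: dict[str, object] = {
        "annotation": str(outdir / "genes.bed12"),
        "counts": str(outdir / "counts.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "genotype_ref": config.genotype_ref,
        "genotype_test": config.genotype_test,
        "de_threshold": 1.5,
        "test_threshold": 3.0,
        "flank": config.flank,
        "seed": config.seed,
    }
    for (mark, fraction, genotype), lib in study.libraries.items():
        name = f"reads_{mark}_{fraction}_{genotype}.bed"
        write_reads_bed(lib, outdir / name)
        pipeline_config[f"reads_{mark}_{fraction}_{genotype}"] = str(outdir / name)
    with open(outdir / "config.yaml", "wt") as fh:
        yaml.safe_dump(pipeline_config, fh, sort_keys=True)
    return {k: str(v) for k, v in pipeline_config.items()}
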