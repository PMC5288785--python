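"""Shared fixtures: a small deterministic synthetic study and helpers."""

import numpy as np
import pytest

from markgene.genome import AlignedReadSet, GeneModel, GenomicInterval
from markgene.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=60,
        chrom_length=2_000_000,
        n_chroms=2,
        reads_per_chip_library=20_000,
        reads_per_input_library=20_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture
def plus_gene() -> GeneModel:
    return GeneModel("geneA", GenomicInterval("chr1", 10_000, 15_000, "+"), 5_000)


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel("geneB", GenomicInterval("chr1", 10_000, 15_000, "-"), 5_000)


def random_reads(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                 span: int = 1_000_000, read_len: int = 50) -> AlignedReadSet:
    """Uniform random reads for oracle comparisons."""
    chrom = rng.choice(np.asarray(chroms, dtype=object), size=n)
    starts = rng.integers(0, span - read_len, size=n)
    return AlignedReadSet("random", chrom, starts, starts + read_len)
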