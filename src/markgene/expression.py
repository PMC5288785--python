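"""FPKM quantification, inter-genotype fold change, and DE classification.

FPKM_g = counts_g * 1e9 / (transcript_length_g * total_fragments).  Fold
changes are (test + pseudocount) / (ref + pseudocount) so zeros stay finite;
classification at threshold t is strict: up if fc > t, down if fc < 1/t,
unchanged otherwise.  Replicates within a genotype are averaged on the FPKM
scale before fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_fpkm",
    "fold_change",
    "classify_de",
    "log_correlation",
    "ExpressionTable",
    "FoldChangeTable",
    "read_count_table",
    "read_sample_sheet",
]

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"


def compute_fpkm(counts, transcript_lengths, total_fragments: int):
    """Fragments per kilobase of transcript per million mapped fragments.

    ``counts * 1e9 / (length * total_fragments)``; vectorised over genes.
    """
    if total_fragments < 1:
        raise ValueError(f"total_fragments must be >= 1, got {total_fragments}")
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(transcript_lengths, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(lengths < 1):
        raise ValueError("transcript lengths must be >= 1 bp")
    return counts * 1e9 / (lengths * float(total_fragments))


def fold_change(test_fpkm, ref_fpkm, pseudocount: float = 0.1):
    """(test + pseudocount) / (ref + pseudocount); scalars or arrays."""
    test = np.asarray(test_fpkm, dtype=float)
    ref = np.asarray(ref_fpkm, dtype=float)
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    if np.any(test < 0) or np.any(ref < 0):
        raise ValueError("FPKM inputs must be non-negative")
    denom = ref + pseudocount
    if np.any(denom == 0):
        raise ValueError("ref + pseudocount is zero; use a positive pseudocount")
    out = (test + pseudocount) / denom
    return float(out) if out.ndim == 0 else out


def classify_de(fc, threshold: float = 1.5):
    """Label fold changes: up (fc > t), down (fc < 1/t), else unchanged."""
    if threshold <= 1:
        raise ValueError(f"threshold must be > 1, got {threshold}")
    fc_arr = np.asarray(fc, dtype=float)
    out = np.where(
        fc_arr > threshold, UP, np.where(fc_arr < 1.0 / threshold, DOWN, UNCHANGED)
    )
    if out.ndim == 0:
        return str(out)
    if isinstance(fc, pd.Series):
        return pd.Series(out, index=fc.index, name="de_class")
    return out


def log_correlation(sample_a, sample_b, pseudocount: float = 1.0) -> float:
    """Pearson r of log10(FPKM + pseudocount) between two samples.

    Restricted to genes expressed (FPKM > 0) in at least one of the two
    samples; needs >= 3 such genes and non-constant log vectors.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must cover the same genes")
    mask = (a > 0) | (b > 0)
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 expressed genes, got {int(mask.sum())}")
    x = np.log10(a[mask] + pseudocount)
    y = np.log10(b[mask] + pseudocount)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in log-expression vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class FoldChangeTable:
    """Per-gene fold changes between two genotypes plus DE classes."""

    frame: pd.DataFrame  # columns: fc, log2fc, de_class
    test_genotype: str
    ref_genotype: str
    threshold: float
    pseudocount: float

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def fc(self) -> pd.Series:
        return self.frame["fc"]

    @property
    def log2fc(self) -> pd.Series:
        return self.frame["log2fc"]

    @property
    def de_class(self) -> pd.Series:
        return self.frame["de_class"]

    def de_genes(self, de_class: str) -> pd.Index:
        return self.frame.index[self.frame["de_class"] == de_class]


class ExpressionTable:
    """Counts and derived FPKM for genes x samples, with genotype labels.

    ``total_fragments`` per sample is the column sum of the count table.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        transcript_lengths: pd.Series,
        sample_genotypes: Mapping[str, str],
    ) -> None:
        if counts.isna().any().any() or (counts < 0).any().any():
            raise ValueError("counts must be non-negative and complete")
        missing = [s for s in counts.columns if s not in sample_genotypes]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing}")
        lengths = transcript_lengths.reindex(counts.index)
        if lengths.isna().any():
            bad = lengths.index[lengths.isna()][:5].tolist()
            raise ValueError(f"transcript lengths missing for genes {bad}")
        self.counts = counts
        self.transcript_lengths = lengths.astype(float)
        self.sample_genotypes = dict(sample_genotypes)
        fpkm = {}
        for sample in counts.columns:
            total = int(counts[sample].sum())
            if total < 1:
                raise ValueError(f"sample {sample}: zero total fragments")
            fpkm[sample] = compute_fpkm(
                counts[sample].to_numpy(), self.transcript_lengths.to_numpy(), total
            )
        self.fpkm = pd.DataFrame(fpkm, index=counts.index)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def samples_of(self, genotype: str) -> list[str]:
        out = [s for s, g in self.sample_genotypes.items() if g == genotype]
        if not out:
            raise ValueError(f"no samples with genotype {genotype!r}")
        return out

    def genotype_fpkm(self, genotype: str) -> pd.Series:
        """Mean FPKM across a genotype's replicate samples."""
        cols = [s for s in self.fpkm.columns if self.sample_genotypes[s] == genotype]
        if not cols:
            raise ValueError(f"no samples with genotype {genotype!r}")
        return self.fpkm[cols].mean(axis=1)

    def fold_changes(
        self,
        test_genotype: str,
        ref_genotype: str,
        pseudocount: float = 0.1,
        threshold: float = 1.5,
    ) -> FoldChangeTable:
        test = self.genotype_fpkm(test_genotype)
        ref = self.genotype_fpkm(ref_genotype)
        fc = fold_change(test.to_numpy(), ref.to_numpy(), pseudocount)
        frame = pd.DataFrame(
            {
                "fc": fc,
                "log2fc": np.log2(fc),
                "de_class": classify_de(fc, threshold),
            },
            index=self.counts.index,
        )
        return FoldChangeTable(frame, test_genotype, ref_genotype, threshold, pseudocount)


def read_count_table(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a TSV count table: gene_id, length, one column per sample."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "length"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: count table needs columns {sorted(required)}")
    df = df.set_index("gene_id")
    lengths = df["length"].astype(float)
    counts = df.drop(columns=["length"])
    return counts, lengths


def read_sample_sheet(path) -> dict[str, str]:
    """Read a TSV sample sheet with columns sample_id, genotype."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "genotype"}.issubset(df.columns):
        raise ValueError(f"{path}: sample sheet needs sample_id and genotype columns")
    return dict(zip(df["sample_id"].astype(str), df["genotype"].astype(str)))
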