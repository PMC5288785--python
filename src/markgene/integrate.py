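"""Genotype comparison of mark enrichment within expression classes, and
joint fold-change reporting.

The class-wise comparison is an unpaired Welch t-test on per-gene log2
enrichment, genotype A vs genotype B, restricted to the genes of each DE
class (a paired variant is available via ``paired=True``).  Ratios are
log2-transformed before testing to stabilise variance; raw Welch p-values
are reported without multiple-testing correction (an optional
Benjamini-Hochberg helper is provided).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DOWN, UP, FoldChangeTable

__all__ = [
    "TestResult",
    "welch_t",
    "mark_vs_expression_test",
    "joint_fold_change",
    "benjamini_hochberg",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    """Two-sample t-test summary."""

    statistic: float
    df: float
    p_value: float
    n1: int
    n2: int
    mean_a: float
    mean_b: float


def welch_t(group_a, group_b, equal_var: bool = False) -> TestResult:
    """Two-sided two-sample t-test.

    Default is the Welch form (unequal variances, Welch-Satterthwaite
    degrees of freedom); ``equal_var=True`` gives the pooled-variance
    Student form.  Each group needs >= 2 values.  If both groups are
    constant with equal means the result is t = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 values, got {n1} and {n2}")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    m1, m2 = float(a.mean()), float(b.mean())
    if v1 == 0 and v2 == 0:
        if m1 == m2:
            return TestResult(0.0, float(n1 + n2 - 2), 1.0, n1, n2, m1, m2)
        t = np.inf if m1 > m2 else -np.inf
        return TestResult(float(t), float(n1 + n2 - 2), 0.0, n1, n2, m1, m2)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        se1, se2 = v1 / n1, v2 / n2
        df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    return TestResult(
        float(res.statistic), float(df), float(res.pvalue), n1, n2, m1, m2
    )


def _paired_t(diff: np.ndarray) -> TestResult:
    n = diff.size
    res = stats.ttest_1samp(diff, 0.0)
    return TestResult(
        float(res.statistic),
        float(n - 1),
        float(res.pvalue),
        n,
        n,
        float(diff.mean()),
        0.0,
    )


def mark_vs_expression_test(
    enrichment_a: pd.Series,
    enrichment_b: pd.Series,
    de_class: pd.Series,
    classes: Sequence[str] = (UP, DOWN),
    log2: bool = True,
    paired: bool = False,
    equal_var: bool = False,
) -> dict[str, TestResult]:
    """Compare per-gene enrichment between genotypes within each DE class.

    ``enrichment_a``/``enrichment_b`` are per-gene enrichment values for the
    two genotypes; ``de_class`` maps genes to up/down/unchanged.  For each
    requested class with >= 2 genes, a Welch test of (log2) enrichment A vs
    B is returned; smaller classes are skipped with a warning.
    """
    genes = de_class.index
    a = enrichment_a.reindex(genes)
    b = enrichment_b.reindex(genes)
    if a.isna().any() or b.isna().any():
        missing = genes[a.isna() | b.isna()][:5].tolist()
        raise ValueError(f"enrichment missing for genes {missing}")
    if log2:
        a = np.log2(a)
        b = np.log2(b)
    results: dict[str, TestResult] = {}
    for cls in classes:
        sel = de_class == cls
        n = int(sel.sum())
        if n < 2:
            logger.warning("class %r has %d gene(s); skipping test", cls, n)
            continue
        x = a[sel].to_numpy()
        y = b[sel].to_numpy()
        if paired:
            results[cls] = _paired_t(x - y)
        else:
            results[cls] = welch_t(x, y, equal_var=equal_var)
    return results


def joint_fold_change(
    expression_fc: FoldChangeTable,
    k4_fc: pd.Series,
    k27_fc: pd.Series,
    gene_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Merge expression and per-mark enrichment fold changes on log2 scale.

    The gene universe is the intersection of the three component tables (in
    expression order).  With ``gene_subset`` the output is restricted to
    those genes; any subset gene absent from a component table is an error
    listing the missing ids.
    """
    universe = expression_fc.gene_ids
    universe = universe[universe.isin(k4_fc.index) & universe.isin(k27_fc.index)]
    if gene_subset is not None:
        subset = pd.Index(gene_subset)
        missing = subset[~subset.isin(universe)]
        if len(missing):
            raise ValueError(
                f"genes absent from component tables: {missing.tolist()}"
            )
        universe = subset
    out = pd.DataFrame(
        {
            "expression_log2fc": expression_fc.log2fc.reindex(universe),
            "k4_log2fc": np.log2(k4_fc.reindex(universe)),
            "k27_log2fc": np.log2(k27_fc.reindex(universe)),
            "de_class": expression_fc.de_class.reindex(universe),
        }
    )
    out.index.name = "gene_id"
    return out


def benjamini_hochberg(p_values: Mapping[str, float]) -> dict[str, float]:
    """BH-adjusted q-values for a small family of tests (off by default in
    the pipeline; provided for completeness)."""
    keys = list(p_values)
    p = np.asarray([p_values[k] for k in keys], dtype=float)
    order = np.argsort(p)
    m = p.size
    q = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        prev = min(prev, p[i] * m / (rank_idx + 1))
        q[i] = prev
    return dict(zip(keys, q.tolist()))
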