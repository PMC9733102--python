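"""Dataset-level QC and cross-dataset comparison statistics.

Variance-equality F-tests between datasets, Kolmogorov–Smirnov normality
checks, raw-expression correlation over shared genes, Venn-style overlap
counts of tissue-specific gene lists, and consensus gene calls supported
by several independent datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    InsufficientOverlapError,
)
from .io import ExpressionMatrix, GeneTissueAssignment
from .tau import log_transform

__all__ = [
    "DatasetComparison",
    "f_test_equal_variance",
    "ks_normality",
    "expression_correlation",
    "overlap_counts",
    "consensus_genes",
]


@dataclass
class DatasetComparison:
    """Pairwise comparison of two expression datasets over shared genes."""

    dataset_ids: tuple[str, str]
    f_statistic: float
    f_pvalue: float
    correlation: float
    shared_genes: int


def f_test_equal_variance(a, b) -> tuple[float, float]:
    """Two-sided F-test of variance equality between two samples.

    The larger sample variance goes in the numerator, so F >= 1 and the
    test is symmetric in its arguments. Returns (F, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("F-test needs >= 2 values per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        num_var, den_var, dfn, dfd = va, vb, a.size - 1, b.size - 1
    else:
        num_var, den_var, dfn, dfd = vb, va, b.size - 1, a.size - 1
    if den_var == 0.0:
        raise DegenerateVarianceError("denominator sample has zero variance")
    f = num_var / den_var
    p = 2.0 * sps.f.sf(f, dfn, dfd)
    return float(f), float(min(p, 1.0))


def ks_normality(values, transform: str = "none") -> tuple[float, float]:
    """One-sample K-S test against a normal with the sample's own mean/SD.

    ``transform="log2"`` applies log2(x + 1) first, matching how
    expression distributions are usually inspected on Q-Q plots. The
    classical (uncorrected) K-S p-value is reported; with estimated
    parameters it is known to be conservative.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 8:
        raise InsufficientDataError("K-S normality check needs >= 8 values")
    if transform == "log2":
        arr = log_transform(arr)
    elif transform != "none":
        raise ValueError("transform must be 'none' or 'log2'")
    mu, sd = arr.mean(), arr.std(ddof=1)
    if sd == 0.0:
        raise DegenerateVarianceError("constant sample cannot be tested for normality")
    stat, p = sps.kstest(arr, "norm", args=(mu, sd))
    return float(stat), float(p)


def expression_correlation(a: ExpressionMatrix, b: ExpressionMatrix) -> DatasetComparison:
    """Pearson correlation of two datasets' per-gene mean expression.

    Datasets share genes, not tissue panels, so each gene is summarised by
    its mean over that dataset's own tissues before correlating. Needs at
    least three shared gene ids.
    """
    shared = a.values.index.intersection(b.values.index)
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared genes; need >= 3 to correlate"
        )
    mean_a = a.values.loc[shared].mean(axis=1).to_numpy()
    mean_b = b.values.loc[shared].mean(axis=1).to_numpy()
    r = float(sps.pearsonr(mean_a, mean_b).statistic)
    f, p = f_test_equal_variance(mean_a, mean_b)
    return DatasetComparison(
        dataset_ids=(a.units, b.units),
        f_statistic=f,
        f_pvalue=p,
        correlation=r,
        shared_genes=int(len(shared)),
    )


def overlap_counts(gene_lists: Sequence[Iterable]) -> dict[frozenset, int]:
    """Venn-region counts for 2–5 gene sets.

    Returns a count for every nonempty membership pattern (a frozenset of
    0-based dataset indices); counts over all patterns sum to the size of
    the union. Empty regions are reported with count 0.
    """
    sets = [set(g) for g in gene_lists]
    k = len(sets)
    if not 2 <= k <= 5:
        raise InsufficientDataError("overlap_counts supports 2-5 gene sets")
    counts: dict[frozenset, int] = {}
    for r in range(1, k + 1):
        for pattern in combinations(range(k), r):
            counts[frozenset(pattern)] = 0
    for gene in set().union(*sets):
        pattern = frozenset(i for i, s in enumerate(sets) if gene in s)
        counts[pattern] += 1
    return counts


def consensus_genes(
    assignments: Sequence[GeneTissueAssignment],
    tissue: str,
    min_support: int,
) -> pd.Series:
    """Genes assigned to ``tissue`` by at least ``min_support`` datasets.

    Returns a Series mapping gene id -> exact support count, restricted to
    genes meeting the support floor and sorted by decreasing support.
    Warns (and returns empty) when no dataset mentions the tissue at all.
    """
    if not 1 <= min_support:
        raise ValueError("min_support must be >= 1")
    per_dataset = [
        set(a.table.loc[a.table["tissue"] == tissue, "gene_id"]) for a in assignments
    ]
    if all(
        tissue not in set(a.table["tissue"]) for a in assignments
    ):
        warnings.warn(f"tissue {tissue!r} absent from all datasets", stacklevel=2)
        return pd.Series(dtype=int, name="support")
    support: dict[str, int] = {}
    for genes in per_dataset:
        for g in genes:
            support[g] = support.get(g, 0) + 1
    kept = {g: s for g, s in support.items() if s >= min_support}
    out = pd.Series(kept, dtype=int, name="support")
    return out.sort_values(ascending=False, kind="stable")
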