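"""Multi-tissue assignment of specific genes — the extended tau procedure.

The classic tau index flags a gene as tissue-specific but can only point
at the single tissue of maximum expression. The extension estimates, per
dataset, a statistically significant interval below each specific gene's
maximum and assigns the gene to *every* tissue whose raw expression falls
inside it:

1. Within each tissue, cluster the nonzero expression values of all genes
   into two fuzzy clusters and record the upper-cluster fraction
   ``ratio = n_up / n_total``.
2. Optimise a dataset-level threshold ratio over tissues (mean by
   default) and convert it to a normal quantile
   ``z_val = Phi^-1(1 - ratio_opt)`` — a small upper-cluster fraction
   means the truly high expressers sit far out in the tail, giving a
   large z and a generous interval below the maximum.
3. For each specific gene compute ``dist_ss = x_max - sigma * z_val``
   where sigma is the sample standard deviation of the gene's nonzero
   expression, and assign the gene to every tissue with raw expression
   >= dist_ss (the argmax tissue is always included).

Restricting the result to each gene's argmax tissue reproduces the
original single-tissue tau assignment exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DimensionError, InsufficientDataError, MalformedInputError
from .fcm import TissueClusterResult, fcm_two_cluster, tissue_upper_ratio
from .io import PAIR_COLUMNS, ExpressionMatrix, GeneTissueAssignment
from .tau import TauCategorizer, _as_frame

__all__ = [
    "DatasetThreshold",
    "optimize_ratio_threshold",
    "ratio_to_z",
    "gene_sigma_nonzero",
    "compute_dist_ss",
    "assign_specific_tissues",
    "ExtendedTau",
    "run_extended_tau",
]

logger = logging.getLogger(__name__)

_CLAMP_EPS = 1e-6
THRESHOLD_METHODS = ("mean", "median", "linear-trend")


@dataclass
class DatasetThreshold:
    """Optimised upper-cluster ratio for one dataset and its z-value."""

    ratio_opt: float
    z_val: float
    method: str


def ratio_to_z(ratio_opt: float) -> float:
    """Upper-tail standard-normal quantile of a ratio: Phi^-1(1 - ratio).

    Smaller upper-cluster ratios give larger z; at z = 0 (ratio 0.5) the
    interval collapses to the maximum itself and the assignment reduces
    to the classic single-tissue tau call.
    """
    if not 0.0 < ratio_opt < 1.0:
        raise MalformedInputError("ratio must lie strictly in (0, 1)")
    return float(stats.norm.isf(ratio_opt))


def optimize_ratio_threshold(ratios, method: str = "mean") -> DatasetThreshold:
    """Collapse per-tissue upper-cluster ratios to one dataset threshold.

    Methods: ``mean`` (default), ``median``, and ``linear-trend`` — a
    least-squares fit of the sorted ratios against their rank, evaluated
    at the mid-rank. The result is clamped to (1e-6, 1 - 1e-6) before the
    quantile conversion.
    """
    arr = np.asarray([r for r in ratios if r is not None], dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no non-degenerate ratios to optimise over")
    if method == "mean":
        opt = float(arr.mean())
    elif method == "median":
        opt = float(np.median(arr))
    elif method == "linear-trend":
        ranks = np.arange(arr.size, dtype=float)
        slope, intercept = np.polyfit(ranks, np.sort(arr), 1) if arr.size > 1 else (0.0, arr[0])
        opt = float(intercept + slope * ranks.mean())
    else:
        raise ValueError(f"unknown threshold method {method!r}; use one of {THRESHOLD_METHODS}")
    opt = float(np.clip(opt, _CLAMP_EPS, 1.0 - _CLAMP_EPS))
    return DatasetThreshold(ratio_opt=opt, z_val=ratio_to_z(opt), method=method)


def gene_sigma_nonzero(values) -> float:
    """Sample (n-1) standard deviation over a gene's strictly positive values.

    Defined as 0 when fewer than two nonzero values exist; an all-zero
    gene has no maximum and is a domain error (it can never be specific).
    """
    arr = np.asarray(values, dtype=float)
    nz = arr[arr > 0]
    if nz.size == 0:
        raise MalformedInputError("sigma undefined for an all-zero gene")
    if nz.size < 2:
        return 0.0
    return float(nz.std(ddof=1))


def compute_dist_ss(x_max: float, sigma: float, z_val: float) -> float:
    """Statistically significant distance below the maximum: x_max - sigma*z."""
    return float(x_max - sigma * z_val)


def assign_specific_tissues(expression: pd.Series, dist_ss: float) -> list[str]:
    """Tissues whose raw expression reaches dist_ss, plus the argmax tissue(s).

    The boundary is inclusive; ties at the maximum assign every tied
    tissue. With a dist_ss above the maximum (possible for a negative z)
    only the argmax tissue(s) remain.
    """
    arr = expression.to_numpy(dtype=float)
    keep = arr >= dist_ss
    keep |= arr == arr.max()
    return list(expression.index[keep])


class ExtendedTau(BaseEstimator):
    """Estimator running the full extended tau pipeline on one dataset.

    Parameters
    ----------
    null_cutoff, weak_cutoff, tau_cutoff, pseudocount
        Categorization settings (see :class:`~tissuetau.tau.TauCategorizer`).
    threshold_method
        ``"mean"`` (default), ``"median"`` or ``"linear-trend"``; how the
        per-tissue upper-cluster ratios collapse to one dataset ratio.
    z_val
        Optional fixed z-value. When given, clustering and threshold
        optimisation are skipped entirely (use to replay a published
        per-dataset z).
    clustering_axis
        ``"tissue"`` (default): cluster nonzero values of all genes within
        each tissue. ``"gene"``: cluster each gene's nonzero values across
        tissues instead.
    fcm_m, fcm_tol, fcm_max_iter
        Fuzzy c-means configuration.

    Attributes
    ----------
    tau_, categories_, category_counts_ : per-gene categorization output.
    cluster_results_ : list of :class:`TissueClusterResult`.
    ratio_opt_, z_val_ : the optimised dataset threshold and its quantile.
    assignments_ : :class:`GeneTissueAssignment` — the gene-tissue pairs.
    summary_ : dict of headline counts.
    """

    def __init__(
        self,
        null_cutoff: float = 1.0,
        weak_cutoff: float = 10.0,
        tau_cutoff: float = 0.85,
        pseudocount: float = 1.0,
        threshold_method: str = "mean",
        z_val: float | None = None,
        clustering_axis: str = "tissue",
        fcm_m: float = 2.0,
        fcm_tol: float = 1e-6,
        fcm_max_iter: int = 1000,
    ):
        self.null_cutoff = null_cutoff
        self.weak_cutoff = weak_cutoff
        self.tau_cutoff = tau_cutoff
        self.pseudocount = pseudocount
        self.threshold_method = threshold_method
        self.z_val = z_val
        self.clustering_axis = clustering_axis
        self.fcm_m = fcm_m
        self.fcm_tol = fcm_tol
        self.fcm_max_iter = fcm_max_iter

    # ------------------------------------------------------------------
    def fit(self, X, y=None) -> "ExtendedTau":
        values = _as_frame(X)
        gene_names = X.gene_names if isinstance(X, ExpressionMatrix) else None
        if values.shape[1] < 2:
            raise DimensionError("extended tau needs >= 2 tissues")

        cat = TauCategorizer(
            null_cutoff=self.null_cutoff,
            weak_cutoff=self.weak_cutoff,
            tau_cutoff=self.tau_cutoff,
            pseudocount=self.pseudocount,
        ).fit(values)
        self.tau_ = cat.tau_
        self.categories_ = cat.categories_
        self.category_counts_ = cat.category_counts_

        if self.z_val is not None:
            self.cluster_results_ = []
            self.ratio_opt_ = None
            self.z_val_ = float(self.z_val)
            logger.info("using user-supplied z_val=%.4f", self.z_val_)
        else:
            self.cluster_results_ = self._cluster(values)
            ratios = [r.ratio for r in self.cluster_results_ if not r.degenerate]
            try:
                threshold = optimize_ratio_threshold(ratios, self.threshold_method)
            except InsufficientDataError:
                if (self.categories_ == "specific").any():
                    raise
                # nothing to assign anyway; threshold stays undefined
                threshold = DatasetThreshold(None, float("nan"), self.threshold_method)
            self.ratio_opt_ = threshold.ratio_opt
            self.z_val_ = threshold.z_val
            logger.info(
                "upper-cluster ratio=%s (%s over %d units) -> z=%.4f",
                self.ratio_opt_, self.threshold_method, len(ratios), self.z_val_,
            )

        self.assignments_ = self._assign(values, gene_names)
        n_specific = int((self.categories_ == "specific").sum())
        self.summary_ = {
            "n_genes": int(values.shape[0]),
            "n_tissues": int(values.shape[1]),
            **{f"n_{k}": int(v) for k, v in self.category_counts_.items()},
            "n_specific_genes": n_specific,
            "n_pairs": self.assignments_.n_pairs,
            "ratio_opt": self.ratio_opt_,
            "z_val": self.z_val_,
        }
        self.n_features_in_ = values.shape[1]
        return self

    def fit_predict(self, X, y=None) -> GeneTissueAssignment:
        return self.fit(X).assignments_

    # ------------------------------------------------------------------
    def _cluster(self, values: pd.DataFrame) -> list[TissueClusterResult]:
        if self.clustering_axis == "tissue":
            series = ((t, values[t]) for t in values.columns)
        elif self.clustering_axis == "gene":
            series = ((g, values.loc[g]) for g in values.index)
        else:
            raise ValueError("clustering_axis must be 'tissue' or 'gene'")
        results = []
        for label, vec in series:
            arr = vec.to_numpy(dtype=float)
            results.append(
                fcm_two_cluster(
                    arr[arr > 0],
                    tissue_id=str(label),
                    m=self.fcm_m,
                    tol=self.fcm_tol,
                    max_iter=self.fcm_max_iter,
                )
            )
        return results

    def _assign(self, values: pd.DataFrame, gene_names) -> GeneTissueAssignment:
        specific = self.categories_[self.categories_ == "specific"].index
        if len(specific) == 0:
            warnings.warn("no specific genes in matrix; empty assignment", stacklevel=2)
            return GeneTissueAssignment(pd.DataFrame(columns=PAIR_COLUMNS))

        rows = []
        for gene in specific:
            expr = values.loc[gene]
            x_max = float(expr.max())
            sigma = gene_sigma_nonzero(expr)
            dist = compute_dist_ss(x_max, sigma, self.z_val_)
            name = "" if gene_names is None else str(gene_names.loc[gene])
            tau = float(self.tau_.loc[gene])
            for tissue in assign_specific_tissues(expr, dist):
                e = float(expr[tissue])
                rows.append((gene, name, tissue, e, tau, dist, x_max, sigma, e == x_max))
        table = pd.DataFrame(rows, columns=PAIR_COLUMNS)
        return GeneTissueAssignment(table)


def run_extended_tau(
    matrix: ExpressionMatrix | pd.DataFrame, **params
) -> tuple[GeneTissueAssignment, dict]:
    """Functional wrapper: fit :class:`ExtendedTau` and return (assignment, summary)."""
    est = ExtendedTau(**params).fit(matrix)
    return est.assignments_, est.summary_
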