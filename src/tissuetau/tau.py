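"""Gene categorization by expression level and the tau specificity index.

Every gene in a multi-tissue expression matrix is placed in exactly one of
four classes:

* ``null`` — expressed <= 1.0 FPKM/TPM in all tissues;
* ``weak`` — below 10 in all tissues (tau is still computed but carries no
  weight for specificity);
* ``specific`` — tau >= 0.85;
* ``wide_spread`` — everything else.

Tau is computed on log2(x + 1)-transformed expression,

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1),

so tau = 0 for perfectly uniform expression and tau = 1 when a single
tissue carries all (transformed) expression. All category cutoffs operate
on the raw values; the log transform is used only inside tau.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import DimensionError, MalformedInputError
from .io import ExpressionMatrix

__all__ = [
    "CATEGORIES",
    "log_transform",
    "compute_tau",
    "compute_tau_matrix",
    "categorize_gene",
    "categorize_matrix",
    "TauCategorizer",
]

CATEGORIES = ("null", "weak", "wide_spread", "specific")


def log_transform(values, pseudocount: float = 1.0) -> np.ndarray:
    """Elementwise log2(x + pseudocount-shifted) transform.

    With the default pseudocount of 1, zero maps to zero and the transform
    is monotone on [0, inf). Negative inputs are a domain error.
    """
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise MalformedInputError("log_transform requires non-negative values")
    return np.log2(arr + pseudocount)


def compute_tau(values, pseudocount: float = 1.0) -> float:
    """Tau specificity index of one gene's expression across >= 2 tissues.

    Returns NaN (not-a-score) when the transformed vector is all zero;
    such genes are null-expressed and never reach specificity assessment.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise DimensionError("tau needs a 1-D vector over >= 2 tissues")
    x = log_transform(arr, pseudocount)
    xmax = x.max()
    if xmax == 0.0:
        return float("nan")
    xhat = x / xmax
    return float((1.0 - xhat).sum() / (x.size - 1))


def compute_tau_matrix(values: pd.DataFrame, pseudocount: float = 1.0) -> pd.Series:
    """Vectorised tau over every row of a genes × tissues DataFrame."""
    if values.shape[1] < 2:
        raise DimensionError("tau needs >= 2 tissue columns")
    x = log_transform(values.to_numpy(), pseudocount)
    xmax = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - x / xmax[:, None]).sum(axis=1) / (n - 1)
    tau[xmax == 0.0] = np.nan
    return pd.Series(tau, index=values.index, name="tau")


def categorize_gene(
    raw_values,
    tau: float,
    null_cutoff: float = 1.0,
    weak_cutoff: float = 10.0,
    tau_cutoff: float = 0.85,
    require_all_above_weak: bool = False,
) -> str:
    """Assign one gene to null / weak / specific / wide_spread.

    Cutoffs follow the printed conventions: null is inclusive (<= 1.0),
    weak is strict (< 10 in every tissue), specific is tau >= 0.85.
    ``require_all_above_weak`` enables the literal reading in which a
    specific call additionally demands expression above the weak cutoff in
    every tissue; the default treats "non-weak" as "maximum above 10",
    which is the only reading compatible with near-zero off-tissue
    expression of specific genes.
    """
    arr = np.asarray(raw_values, dtype=float)
    if (arr <= null_cutoff).all():
        return "null"
    if (arr < weak_cutoff).all():
        return "weak"
    if not np.isnan(tau) and tau >= tau_cutoff:
        if require_all_above_weak and not (arr > weak_cutoff).all():
            return "wide_spread"
        return "specific"
    return "wide_spread"


def categorize_matrix(
    matrix: ExpressionMatrix | pd.DataFrame, **kwargs
) -> tuple[pd.DataFrame, pd.Series]:
    """Categorize every gene of a matrix; returns (table, count summary).

    The table has columns ``tau`` and ``category``; the summary counts the
    four categories (always all four, zero-filled) and sums to the number
    of genes.
    """
    est = TauCategorizer(**kwargs).fit(matrix)
    table = pd.DataFrame({"tau": est.tau_, "category": est.categories_})
    return table, est.category_counts_


class TauCategorizer(BaseEstimator):
    """Estimator that partitions genes into the four expression classes.

    Parameters
    ----------
    null_cutoff, weak_cutoff, tau_cutoff
        Raw-expression and tau thresholds (defaults 1.0, 10, 0.85).
    pseudocount
        Added before the log2 transform inside tau.
    require_all_above_weak
        Literal "above the weak cutoff in every tissue" gate on specific
        calls; off by default (see :func:`categorize_gene`).

    Attributes
    ----------
    tau_ : pandas.Series
        Per-gene tau (NaN for all-zero transformed rows).
    categories_ : pandas.Series
        Per-gene category label.
    category_counts_ : pandas.Series
        Counts over the four categories, summing to ``n_genes_``.
    """

    def __init__(
        self,
        null_cutoff: float = 1.0,
        weak_cutoff: float = 10.0,
        tau_cutoff: float = 0.85,
        pseudocount: float = 1.0,
        require_all_above_weak: bool = False,
    ):
        self.null_cutoff = null_cutoff
        self.weak_cutoff = weak_cutoff
        self.tau_cutoff = tau_cutoff
        self.pseudocount = pseudocount
        self.require_all_above_weak = require_all_above_weak

    def fit(self, X, y=None) -> "TauCategorizer":
        values = _as_frame(X)
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise MalformedInputError("expression values must be finite and >= 0")

        tau = compute_tau_matrix(values, self.pseudocount)
        is_null = (arr <= self.null_cutoff).all(axis=1)
        is_weak = ~is_null & (arr < self.weak_cutoff).all(axis=1)
        is_specific = (
            ~is_null
            & ~is_weak
            & ~tau.isna().to_numpy()
            & (tau.to_numpy() >= self.tau_cutoff)
        )
        if self.require_all_above_weak:
            is_specific &= (arr > self.weak_cutoff).all(axis=1)
        cats = np.where(
            is_null, "null", np.where(is_weak, "weak", np.where(is_specific, "specific", "wide_spread"))
        )
        self.tau_ = tau
        self.categories_ = pd.Series(cats, index=values.index, name="category")
        self.category_counts_ = (
            self.categories_.value_counts().reindex(CATEGORIES, fill_value=0)
        )
        self.n_genes_ = values.shape[0]
        self.n_features_in_ = values.shape[1]
        return self

    def fit_predict(self, X, y=None) -> pd.Series:
        return self.fit(X).categories_


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, ExpressionMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise DimensionError("expected a 2-D genes x tissues array")
    if arr.shape[1] < 2:
        raise DimensionError("expression matrix needs >= 2 tissues")
    return pd.DataFrame(
        arr,
        index=[f"gene_{i}" for i in range(arr.shape[0])],
        columns=[f"tissue_{j}" for j in range(arr.shape[1])],
    )
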