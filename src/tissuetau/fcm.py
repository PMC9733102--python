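"""Deterministic two-cluster fuzzy c-means for 1-D expression values.

Used to split the nonzero expression values observed within one tissue
into a "lower" bulk and an "upper" tail of highly expressed genes; the
fraction of values landing in the upper cluster feeds the dataset-level
threshold optimisation.

Configuration: 2 clusters, fuzzifier m = 2, convergence tolerance 1e-6 on
the centers, max 1000 iterations. Two deterministic starts are run — one
at the 25th/75th percentiles, one at the data extremes — and the solution
with the lower fuzzy objective is kept: on heavy-tailed expression data
the quartile start can stall in a local optimum that splits the low bulk
instead of isolating the highly expressed tail, while the extremal start
finds the lower-objective tail split. Both starts are seed-free, so
identical inputs always give identical clusterings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError

__all__ = ["TissueClusterResult", "fcm_two_cluster", "tissue_upper_ratio"]


@dataclass
class TissueClusterResult:
    """Outcome of two-cluster FCM on one tissue's nonzero values."""

    tissue_id: str
    n_upper: int
    n_total: int
    ratio: float | None
    degenerate: bool
    centers: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.degenerate and self.n_total > 0:
            assert 0 <= self.n_upper <= self.n_total


def tissue_upper_ratio(n_upper: int, n_total: int) -> float:
    """Fraction of a tissue's nonzero-expressing genes in the upper cluster."""
    if n_total <= 0:
        raise InsufficientDataError("upper-cluster ratio undefined for n_total = 0")
    if not 0 <= n_upper <= n_total:
        raise ValueError("need 0 <= n_upper <= n_total")
    return n_upper / n_total


def fcm_two_cluster(
    values,
    tissue_id: str = "",
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> TissueClusterResult:
    """Two-cluster fuzzy c-means over one tissue's nonzero expression values.

    Values are hard-assigned to the cluster of larger membership (ties go
    to the upper cluster, i.e. the one with the larger center). Fewer than
    two values, or all values identical, yields a degenerate result whose
    ratio is None; degenerate tissues are excluded from threshold
    optimisation.
    """
    x = np.asarray(values, dtype=float).ravel()
    n_total = x.size
    if n_total < 2 or np.ptp(x) == 0.0:
        return TissueClusterResult(tissue_id, 0, n_total, None, degenerate=True)

    quartiles = np.percentile(x, [25.0, 75.0])
    extremes = np.array([x.min(), x.max()], dtype=float)
    starts = [extremes] if quartiles[0] == quartiles[1] else [quartiles, extremes]

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for init in starts:
        centers, u, objective = _fcm_iterate(x, init, m, tol, max_iter)
        if best is None or objective < best[0]:
            best = (objective, centers, u)
    _, centers, u = best

    if centers[0] == centers[1]:
        return TissueClusterResult(tissue_id, 0, n_total, None, degenerate=True)
    upper = int(np.argmax(centers))
    in_upper = u[:, upper] >= u[:, 1 - upper]
    n_upper = int(in_upper.sum())
    ratio = tissue_upper_ratio(n_upper, n_total)
    lo, hi = sorted(float(c) for c in centers)
    return TissueClusterResult(tissue_id, n_upper, n_total, ratio, False, (lo, hi))


def _fcm_iterate(
    x: np.ndarray, init: np.ndarray, m: float, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """One FCM run from a fixed start; returns (centers, memberships, objective)."""
    centers = init.astype(float).copy()
    exponent = 2.0 / (m - 1.0)
    u = np.full((x.size, 2), 0.5)
    for _ in range(max_iter):
        u = _memberships(x, centers, exponent)
        w = u**m
        new_centers = (w * x[:, None]).sum(axis=0) / w.sum(axis=0)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    u = _memberships(x, centers, exponent)
    objective = float((u**m * (x[:, None] - centers[None, :]) ** 2).sum())
    return centers, u, objective


def _memberships(x: np.ndarray, centers: np.ndarray, exponent: float) -> np.ndarray:
    d = np.abs(x[:, None] - centers[None, :])
    zero = d == 0.0
    u = np.empty((x.size, 2))
    # u0 = 1 / (1 + (d0/d1)^e) is overflow-safe at any distance scale
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (d[:, 0] / d[:, 1]) ** exponent
        u[:, 0] = 1.0 / (1.0 + r)
    u[:, 1] = 1.0 - u[:, 0]
    on_center = zero.any(axis=1)
    if on_center.any():
        u[on_center] = zero[on_center] / zero[on_center].sum(axis=1, keepdims=True)
    return u
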