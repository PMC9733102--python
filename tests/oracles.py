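"""Independent reference implementations used to check the package.

These deliberately avoid the code paths they validate: tau is evaluated
with 50-digit arbitrary-precision arithmetic straight from the printed
formula, and clustering is checked against the exhaustive minimum-SSE
two-partition (contiguous in 1-D after sorting).
"""

from __future__ import annotations

import math

import mpmath
import numpy as np


def tau_oracle(values, dps: int = 50) -> float:
    """Arbitrary-precision tau: sum(1 - x_i/max)/(n-1) on log2(x+1) values."""
    with mpmath.workdps(dps):
        transformed = [mpmath.log(mpmath.mpf(float(v)) + 1) / mpmath.log(2) for v in values]
        mx = max(transformed)
        if mx == 0:
            return math.nan
        total = sum(1 - t / mx for t in transformed)
        return float(total / (len(transformed) - 1))


def best_two_partition(values) -> tuple[set[int], set[int]]:
    """Exhaustive minimum-SSE split of 1-D points into two nonempty groups.

    The optimal 2-partition under squared error is contiguous in sorted
    order, so all n-1 contiguous splits are enumerated. Returns
    (lower_indices, upper_indices) into the original array.
    """
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    best_sse, best_cut = math.inf, 1
    for cut in range(1, n):
        lo, hi = xs[:cut], xs[cut:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best_sse:
            best_sse, best_cut = sse, cut
    return set(order[:best_cut].tolist()), set(order[best_cut:].tolist())


def well_separated_instance(rng: np.random.Generator, max_points: int = 12):
    """Random 1-D instance with cluster-center gap well above within-cluster spread.

    Returns (values, lower_indices, upper_indices).
    """
    n = int(rng.integers(4, max_points + 1))
    n_hi = int(rng.integers(1, n - 1))
    lo_center = rng.uniform(1.0, 20.0)
    gap = rng.uniform(15.0, 200.0)
    spread = gap / rng.uniform(20.0, 60.0)
    lo = lo_center + rng.normal(0.0, spread, n - n_hi)
    hi = lo_center + gap + rng.normal(0.0, spread, n_hi)
    values = np.abs(np.concatenate([lo, hi])) + 1e-6
    perm = rng.permutation(n)
    values = values[perm]
    lower = {int(i) for i, orig in enumerate(perm) if orig < n - n_hi}
    upper = {int(i) for i, orig in enumerate(perm) if orig >= n - n_hi}
    return values, lower, upper
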