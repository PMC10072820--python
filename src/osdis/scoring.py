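"""Observer-based similarity measures between observed and measured times.

Given a candidate spanning tree rooted at s, each observer o_k has

* an *observation* infection time t_{o_k} — what it actually recorded, and
* a *measuring* infection time t* + sum of delays on the tree path s→o_k,
  where the unknown start time t* is estimated by least squares.

Two similarities compare the K-vectors:

* Infection Time Similarity  S = 1 / (1 + ||T_meas - T_obs||_2), in (0, 1],
  equal to 1 iff the vectors coincide;
* Infection Time Order Similarity  S = (1 + tau) / 2, in [0, 1], where tau
  is the Kendall rank correlation between the two time vectors — i.e. the
  concordance of the two ascending observer orders.

The locator multiplies the two and maximizes over candidate roots.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .exceptions import ScoringError
from .spanning import SpanningTree

__all__ = [
    "path_delays",
    "estimate_t_star",
    "estimate_t_star_grid",
    "time_similarity",
    "kendall_tau",
    "order_similarity",
]


def path_delays(tree: SpanningTree, observers) -> np.ndarray:
    """Cumulative delay from the tree root to each observer, in order.

    The root itself (if an observer) gets 0.
    """
    out = np.empty(len(observers), dtype=float)
    for i, o in enumerate(observers):
        if o not in tree.cum_delay:
            raise ScoringError(f"observer {o} is not covered by the tree")
        out[i] = tree.cum_delay[o]
    return out


def _as_vectors(obs_times, meas_times) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(obs_times, dtype=float)
    b = np.asarray(meas_times, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ScoringError("time vectors must be one-dimensional")
    if a.size != b.size:
        raise ScoringError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ScoringError("empty observer set")
    return a, b


def estimate_t_star(obs_times, path_delays, z: float) -> float:
    """Least-squares start time, clipped to the feasible interval [0, z].

    The objective  sum_k (t* + d_k - t_{o_k})^2  is a convex quadratic in
    t*, minimized at the mean residual  mean_k(t_{o_k} - d_k); the clip
    enforces 0 <= t* <= z.
    """
    t_obs, d = _as_vectors(obs_times, path_delays)
    if z < 0:
        raise ScoringError(f"z must be >= 0, got {z}")
    return float(np.clip(np.mean(t_obs - d), 0.0, z))


def estimate_t_star_grid(obs_times, path_delays, z: float, step: float = 1.0) -> float:
    """Grid-search variant of :func:`estimate_t_star` over t* in [0, z].

    Scans ``0, step, 2*step, ..., z`` and returns the grid point with the
    smallest objective (ties to the smaller t*).  Agrees with the closed
    form to grid resolution; kept for bit-compatibility experiments.
    """
    t_obs, d = _as_vectors(obs_times, path_delays)
    if z < 0:
        raise ScoringError(f"z must be >= 0, got {z}")
    grid = np.arange(0.0, z + step / 2, step)
    if grid[-1] < z:
        grid = np.append(grid, z)
    resid = grid[:, None] + d[None, :] - t_obs[None, :]
    objective = np.sum(resid**2, axis=1)
    return float(grid[int(np.argmin(objective))])


def time_similarity(obs_times, meas_times) -> float:
    """Infection Time Similarity: 1 / (1 + Euclidean distance), in (0, 1]."""
    a, b = _as_vectors(obs_times, meas_times)
    return float(1.0 / (1.0 + np.linalg.norm(b - a)))


def kendall_tau(obs_times, meas_times) -> float:
    """Kendall rank correlation between the two time vectors.

    Computed directly on the times (equivalent to comparing the two
    ascending observer orders); tie-adjusted (tau-b), which coincides
    with the classical (C - D) / (K(K-1)/2) when times are all distinct.
    A single observer imposes no ordering constraint: tau := 1 for K < 2.
    A constant vector carries no ordering information: tau := 0.
    """
    a, b = _as_vectors(obs_times, meas_times)
    if a.size < 2:
        return 1.0
    tau = stats.kendalltau(a, b).statistic
    if np.isnan(tau):  # one vector constant: concordance undefined
        return 0.0
    return float(tau)


def order_similarity(obs_times, meas_times) -> float:
    """Infection Time Order Similarity: (1 + tau) / 2, in [0, 1]."""
    return (1.0 + kendall_tau(obs_times, meas_times)) / 2.0
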