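"""Bayesian change-point detection for rating trajectories.

Uses the run-length formulation of online Bayesian change-point
detection: a constant hazard h governs regime resets and observations
within a regime are Gaussian with conjugate (normal-gamma) unknown mean
and variance, giving Student-t predictives.  The reported change points
are the resets of the maximum a posteriori run-length path (max-product
recursion over run lengths, backtracked from the last observation),
which is robust to the transient jitter of the filtered run-length mode.

The observation scale prior is set from the median absolute deviation of
the first differences of the trajectory and the new-regime mean restarts
at the latest observation, which together make detection invariant to
additive shifts of the whole series.  Hierarchy instability is
summarized by the normalized count: change points divided by the group's
total number of interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import t as student_t


@dataclass(frozen=True)
class CpdParams:
    hazard: float = 1.0 / 50.0   # expected regime length 50 observations
    # weakly informative restart prior: near-diffuse regime mean, heavy-
    # tailed scale (outlier robust); stress-tested on step scenarios
    kappa0: float = 0.05
    alpha0: float = 0.3
    min_scale: float = 1e-8


def detect_change_points(trajectory, params: CpdParams = CpdParams()) -> list[int]:
    """Indices where the trajectory's regime shifts.

    Parameters
    ----------
    trajectory : 1-d sequence of at least 2 observations (e.g. one
        animal's rating after each group interaction).

    Returns
    -------
    Sorted list of change-point indices (position of the first
    observation of each new regime).  A constant trajectory has none.
    """
    x = np.asarray(trajectory, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("trajectory must be 1-d with length >= 2")
    h = params.hazard
    if not (0.0 < h < 1.0):
        raise ValueError("hazard must be in (0, 1)")
    if np.ptp(x) == 0.0:
        return []

    diffs = np.diff(x)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    sigma0 = 1.4826 * mad / np.sqrt(2.0)
    sigma0 = max(sigma0, params.min_scale * max(1.0, np.ptp(x)))
    beta0 = params.alpha0 * sigma0**2

    n = len(x)
    log_h = np.log(h)
    log_1mh = np.log1p(-h)

    # sufficient statistics per run-length hypothesis (index = run length)
    mu = np.array([x[0]])
    kappa = np.array([params.kappa0])
    alpha = np.array([params.alpha0])
    beta = np.array([beta0])
    delta = np.array([0.0])        # best log path score per run length
    backptr = np.zeros(n, dtype=int)  # best predecessor run for a reset at t

    k0, a0 = params.kappa0, params.alpha0
    prior_scale = np.sqrt(beta0 * (k0 + 1.0) / (a0 * k0))
    for t_idx in range(1, n):
        xt = x[t_idx]
        scale = np.sqrt(beta * (kappa + 1.0) / (alpha * kappa))
        log_pred = student_t.logpdf(xt, 2.0 * alpha, loc=mu, scale=scale)
        # a reset starts a fresh regime whose mean prior restarts at the
        # current observation (shift invariant); x_t is its first point
        restart_mu = xt
        log_prior_pred = student_t.logpdf(
            xt, 2.0 * a0, loc=restart_mu, scale=prior_scale
        )
        backptr[t_idx] = int(np.argmax(delta))
        reset = delta.max() + log_h + log_prior_pred
        delta = np.concatenate(([reset], delta + log_1mh + log_pred))
        delta -= delta.max()
        # posterior updates: every surviving hypothesis absorbs x_t
        mu_new = np.concatenate(
            ([(k0 * restart_mu + xt) / (k0 + 1.0)],
             (kappa * mu + xt) / (kappa + 1.0))
        )
        beta_new = np.concatenate(
            ([beta0 + k0 * (xt - restart_mu) ** 2 / (2.0 * (k0 + 1.0))],
             beta + kappa * (xt - mu) ** 2 / (2.0 * (kappa + 1.0)))
        )
        kappa = np.concatenate(([k0 + 1.0], kappa + 1.0))
        alpha = np.concatenate(([a0 + 0.5], alpha + 0.5))
        mu = mu_new
        beta = beta_new

    # backtrack the MAP run-length path
    changes = []
    r = int(np.argmax(delta))
    t_idx = n - 1
    while t_idx > 0:
        if r > 0:
            r -= 1
        else:
            changes.append(t_idx)
            r = backptr[t_idx]
        t_idx -= 1
    changes.reverse()
    return changes


def normalized_change_points(
    n_change_points: int, total_group_interactions: int
) -> float:
    """Change points divided by the group's total number of interactions."""
    if total_group_interactions <= 0:
        raise ValueError("total_group_interactions must be positive")
    return n_change_points / total_group_interactions
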