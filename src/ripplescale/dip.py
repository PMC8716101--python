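"""Hartigan's dip statistic for unimodality.

The dip of a distribution function F is the smallest sup-norm distance
between F and any unimodal distribution function (convex below its mode,
concave above),

    D(F) = min_{G unimodal} sup_x | F(x) - G(x) |.

For a step CDF (empirical or binned, ties allowed) the minimum is found by
bisection on the tolerance ``d``: a unimodal G within ``d`` of F exists iff
for some split of the support a nondecreasing convex branch fits the left
gates ``[F(x_i) - d, F(x_i^-) + d]`` and a nondecreasing concave branch
fits the right gates, with the branch endpoints able to meet inside the
split gap (a steep rise there emulates an atom at the mode).  Convex-branch
feasibility and the minimal attainable branch endpoint reduce to pairwise
slope-forcing conditions: an upper gate at ``x_j`` and a lower gate at
``x_k > x_j`` force every convex candidate to exceed the line through
those gates beyond ``x_k``.  These conditions are evaluated with O(m^2)
vectorized arithmetic per bisection step (m = number of distinct values).

The implementation is validated against a direct linear-programming
solution of the definition on small inputs (see the test suite).
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_from_samples"]

_NEG = -np.inf


def _feasible(x: np.ndarray, lower: np.ndarray, upper: np.ndarray,
              dx: np.ndarray, d: float) -> bool:
    """True when a unimodal CDF exists within sup-distance d of the step CDF.

    Three mode placements are tried at every split of the support: mode
    strictly inside a gap between points (a steep continuous rise emulates
    an atom there), and mode exactly at a point, where G may jump together
    with F, which relaxes that point's upper gate from ``F(x^-) + d`` to
    ``F(x) + d``.
    """
    m = x.size
    lo = np.maximum(lower - d, 0.0)
    up = np.minimum(upper + d, 1.0)
    eps = 1e-12

    # slope forced by the pair (upper gate at x_j, lower gate at x_k > x_j):
    # any candidate CDF through both needs mean slope >= sig[j, k] there
    with np.errstate(invalid="ignore"):
        sig = (lo[None, :] - up[:, None]) / dx   # [j, k], valid for k > j
        sig[~np.tri(m, m, -1, dtype=bool).T] = _NEG

        # convex branch (left to right): slopes only grow, so the forcing
        # into gate k propagates forward; minimal branch value at x_i
        sig_in = np.maximum(sig.max(axis=0), 0.0)       # strongest into k
        ext = lo[None, :] + sig_in[None, :] * (x[:, None] - x[None, :])  # [i, k]
        ext[~np.tri(m, m, -1, dtype=bool)] = _NEG
        e_ext = ext.max(axis=1)                  # extrapolation-only floor
        e_min = np.maximum(lo, e_ext)
        left_ok = np.concatenate(
            [[True], np.cumprod(e_min <= up + eps).astype(bool)])

        # concave branch (right to left, mirror): slopes only shrink, so the
        # forcing out of anchor l propagates backward; maximal value at x_i
        sig_out = np.maximum(sig.max(axis=1), 0.0)      # strongest out of l
        exth = up[None, :] - sig_out[None, :] * dx      # [i, l], l > i
        exth[~np.tri(m, m, -1, dtype=bool).T] = np.inf
        h_noself = exth.min(axis=1)
        h_max = np.minimum(up, h_noself)
        right_ok = np.concatenate(
            [np.cumprod((h_max >= lo - eps)[::-1]).astype(bool)[::-1], [True]])

    # mode in the gap after point s (s = -1..m-1)
    e_end = np.concatenate([[0.0], e_min])
    h_start = np.concatenate([h_max, [1.0]])
    if np.any(left_ok & right_ok & (e_end <= h_start + eps)):
        return True

    # mode with an atom exactly at point t
    up_atom = np.minimum(lower + d, 1.0)
    h_atom = np.minimum(up_atom, h_noself)
    ok = (left_ok[:m] & right_ok[1:]
          & (e_ext <= up + eps) & (e_ext <= h_atom + eps)
          & (lo <= h_atom + eps))
    return bool(np.any(ok))


def dip_statistic(x: np.ndarray, weights: np.ndarray | None = None,
                  tol: float = 1e-10) -> float:
    """Dip of the step CDF with jumps ``weights`` at sorted values ``x``.

    ``x`` must be strictly increasing; ``weights`` (positive, any scale)
    default to equal mass.  Returns 0 for fewer than 2 distinct values.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    if np.any(np.diff(x) <= 0):
        raise ValueError("values must be strictly increasing")
    if weights is None:
        weights = np.ones_like(x)
    weights = np.asarray(weights, dtype=float)
    cdf = np.cumsum(weights)
    cdf /= cdf[-1]
    lower = cdf                                   # F(x_i)
    upper = np.concatenate([[0.0], cdf[:-1]])     # F(x_i^-)
    dx = x[None, :] - x[:, None]
    dx[dx == 0] = np.nan

    lo_d, hi_d = 0.0, 0.25
    if _feasible(x, lower, upper, dx, lo_d):
        return 0.0
    while hi_d - lo_d > tol:
        mid = 0.5 * (lo_d + hi_d)
        if _feasible(x, lower, upper, dx, mid):
            hi_d = mid
        else:
            lo_d = mid
    return float(0.5 * (lo_d + hi_d))


def dip_from_samples(samples: np.ndarray) -> float:
    """Dip of the empirical CDF of a raw sample (ties allowed)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        return 0.0
    vals, counts = np.unique(samples, return_counts=True)
    return dip_statistic(vals, counts)
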