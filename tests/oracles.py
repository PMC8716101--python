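"""Independent oracles used by the test suite.

``dip_lp`` solves Hartigan's dip directly from its definition -- the
minimum over unimodal CDFs G of sup |F - G| -- as a family of linear
programs: for every split of the support and both mode placements (atom at
a data point, or mode strictly inside a gap) the convex-left /
concave-right branch values at the data points are LP variables and the
tolerance d is minimized subject to tube, monotonicity, convexity and
junction constraints.  It is exact but slow, so only small inputs are used.
"""

import itertools

import numpy as np
from scipy.optimize import linprog


def dip_lp(x, w):
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    m = x.size
    cdf = np.cumsum(w) / w.sum()
    L = cdf
    U = np.concatenate([[0.0], cdf[:-1]])
    best = np.inf
    for s, variant in itertools.product(range(m + 1), ("gap", "atom")):
        if variant == "atom" and s == m:
            continue
        has_t = variant == "atom" and 0 < s < m
        ng, nh, nt = s, m - s, 1 if has_t else 0
        nv = ng + nt + nh + 1
        di = nv - 1
        A, b = [], []

        def row(pairs, rhs):
            r = np.zeros(nv)
            for idx, coef in pairs:
                r[idx] += coef
            A.append(r)
            b.append(rhs)

        gi = lambda i: i
        ti = ng
        hi = lambda i: ng + nt + (i - s)
        for i in range(s):
            row([(gi(i), -1), (di, -1)], -L[i])       # g >= L - d
            row([(gi(i), 1), (di, -1)], U[i])         # g <= U + d
            row([(gi(i), -1)], 0.0)                   # g >= 0
        for i in range(s, m):
            row([(hi(i), -1), (di, -1)], -L[i])
            if i >= s + 1 or variant == "gap":
                row([(hi(i), 1), (di, -1)], U[i])
            row([(hi(i), 1)], 1.0)
        for i in range(s - 1):
            row([(gi(i), 1), (gi(i + 1), -1)], 0.0)   # monotone g
        for i in range(s - 2):
            dx0, dx1 = x[i + 1] - x[i], x[i + 2] - x[i + 1]
            row([(gi(i + 1), dx1 + dx0), (gi(i), -dx1), (gi(i + 2), -dx0)], 0.0)
        if has_t:
            row([(gi(s - 1), 1), (ti, -1)], 0.0)
            row([(ti, 1), (di, -1)], U[s])
            row([(ti, 1), (hi(s), -1)], 0.0)
            if s >= 2:
                dx0, dx1 = x[s - 1] - x[s - 2], x[s] - x[s - 1]
                row([(gi(s - 1), dx1 + dx0), (gi(s - 2), -dx1), (ti, -dx0)], 0.0)
        elif variant == "gap" and 0 < s < m:
            row([(gi(s - 1), 1), (hi(s), -1)], 0.0)
        for i in range(s, m - 1):
            row([(hi(i), 1), (hi(i + 1), -1)], 0.0)   # monotone h
        for i in range(s, m - 2):
            dx0, dx1 = x[i + 1] - x[i], x[i + 2] - x[i + 1]
            row([(hi(i + 1), -(dx1 + dx0)), (hi(i), dx1), (hi(i + 2), dx0)], 0.0)
        c = np.zeros(nv)
        c[di] = 1.0
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(None, None)] * (nv - 1) + [(0, None)],
                      method="highs")
        if res.status == 0:
            best = min(best, res.fun)
    return best


def ppc_double_loop(phases):
    """O(N^2) reference PPC: mean pairwise cosine of phase differences."""
    n = len(phases)
    acc = 0.0
    for j in range(n - 1):
        for k in range(j + 1, n):
            acc += np.cos(phases[j] - phases[k])
    return 2.0 * acc / (n * (n - 1))
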