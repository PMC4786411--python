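"""Independent brute-force oracles used by the tests.

The dip oracle answers "is there a unimodal CDF within +-d of the
empirical CDF?" with an explicit linear-program feasibility check over
piecewise-linear candidate CDFs (variables = CDF values at the sample
points, constraints = band, monotonicity, convexity-then-concavity for
every possible mode placement), then binary-searches d. It shares no code
path with the package's convex-minorant computation.
"""

import numpy as np
from scipy.optimize import linprog


def _feasible_at(v, lo, hi, d, mode_kind, i):
    m = v.size
    if mode_kind == "point":
        nv = m + 1
        iL, iR = i, i + 1
        left_pts = list(range(0, i + 1))
        right_pts = list(range(i, m))
    else:
        nv = m
        iL = iR = None
        left_pts = list(range(0, i + 1))
        right_pts = list(range(i + 1, m))

    def var_for(k, side):
        if mode_kind != "point":
            return k
        if k < i:
            return k
        if k > i:
            return k + 1
        return iL if side == "left" else iR

    A_ub, b_ub = [], []

    def add_le(coefs, rhs):
        row = np.zeros(nv)
        for j, c in coefs:
            row[j] += c
        A_ub.append(row)
        b_ub.append(rhs)

    for k in range(m):
        if mode_kind == "point" and k == i:
            add_le([(iL, 1.0)], hi[k] + d)      # left limit below upper band
            add_le([(iR, -1.0)], -(lo[k] - d))  # right value above lower band
        else:
            add_le([(var_for(k, "left"), 1.0)], hi[k] + d)
            add_le([(var_for(k, "left"), -1.0)], -(lo[k] - d))

    order = []
    for k in range(m):
        if mode_kind == "point" and k == i:
            order += [iL, iR]
        else:
            order.append(var_for(k, "left"))
    for a, b in zip(order[:-1], order[1:]):
        add_le([(a, 1.0), (b, -1.0)], 0.0)

    lv = [var_for(k, "left") for k in left_pts]
    for (k0, k1, k2), (j0, j1, j2) in zip(
        zip(left_pts[:-2], left_pts[1:-1], left_pts[2:]),
        zip(lv[:-2], lv[1:-1], lv[2:]),
    ):
        h1, h2 = v[k1] - v[k0], v[k2] - v[k1]
        add_le([(j0, -h2), (j1, h2 + h1), (j2, -h1)], 0.0)  # slopes nondecreasing
    rv = [var_for(k, "right") for k in right_pts]
    for (k0, k1, k2), (j0, j1, j2) in zip(
        zip(right_pts[:-2], right_pts[1:-1], right_pts[2:]),
        zip(rv[:-2], rv[1:-1], rv[2:]),
    ):
        h1, h2 = v[k1] - v[k0], v[k2] - v[k1]
        add_le([(j0, h2), (j1, -(h2 + h1)), (j2, h1)], 0.0)  # slopes nonincreasing

    res = linprog(
        np.zeros(nv), A_ub=np.array(A_ub), b_ub=np.array(b_ub),
        bounds=[(0.0, 1.0)] * nv, method="highs",
    )
    return res.status == 0


def dip_bruteforce(sample, tol=1e-7):
    """Dip statistic by LP feasibility + binary search (small n only)."""
    x = np.sort(np.asarray(sample, float))
    n = x.size
    v, counts = np.unique(x, return_counts=True)
    m = v.size
    if m == 1:
        return 0.0
    cum = np.cumsum(counts)
    lo = cum / n
    hi = (cum - counts) / n

    def feasible(d):
        return any(
            _feasible_at(v, lo, hi, d, "point", i) for i in range(m)
        ) or any(_feasible_at(v, lo, hi, d, "gap", i) for i in range(m - 1))

    a, b = 0.0, 0.5
    while b - a > tol:
        mid = 0.5 * (a + b)
        if feasible(mid):
            b = mid
        else:
            a = mid
    return 0.5 * (a + b)


def ols_strf(S, response, n_delays):
    """Plain least-squares STRF on the lagged design (no regularization)."""
    T, M = S.shape
    X = np.zeros((T, n_delays * M))
    for tau in range(n_delays):
        X[tau:, tau * M:(tau + 1) * M] = S[: T - tau]
    h, *_ = np.linalg.lstsq(X, np.asarray(response, float), rcond=None)
    return h.reshape(n_delays, M)
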