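"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a statistic from its definition by a route that
shares no code with the implementation under test: exhaustive enumeration
for the Mann-Whitney null, explicit mid-rank Pearson for Spearman, and a
linear-programming search over piecewise-linear unimodal CDFs for the dip
statistic.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps
from scipy.optimize import linprog


# ---------------------------------------------------------------------------
# Mann-Whitney by exhaustive enumeration
# ---------------------------------------------------------------------------

def mann_whitney_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Requires tie-free data.  Returns (U of x, p) where p doubles the
    smaller tail probability of the enumerated U distribution, capped at 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle needs tie-free data"
    n_x, n = len(x), len(pooled)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n_x].sum() - n_x * (n_x + 1) / 2

    u_all = []
    for idx in combinations(range(n), n_x):
        u = ranks[list(idx)].sum() - n_x * (n_x + 1) / 2
        u_all.append(u)
    u_all = np.asarray(u_all)
    total = len(u_all)
    cdf = np.sum(u_all <= u_obs + 1e-9) / total
    sf = np.sum(u_all >= u_obs - 1e-9) / total
    return float(u_obs), min(1.0, 2.0 * min(cdf, sf))


def mann_whitney_permutation(x, y, n_draws: int, rng) -> float:
    """Monte-Carlo permutation two-sided p for the Mann-Whitney U.

    Works with ties (mid-ranks); the two-sided p is the fraction of
    permuted U statistics at least as far from the null mean as observed.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n_x, n_y = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    mu = n_x * n_y / 2.0
    u_obs = ranks[:n_x].sum() - n_x * (n_x + 1) / 2

    perm = np.argsort(rng.random((n_draws, n_x + n_y)), axis=1)[:, :n_x]
    u_perm = ranks[perm].sum(axis=1) - n_x * (n_x + 1) / 2
    return float(np.mean(np.abs(u_perm - mu) >= abs(u_obs - mu) - 1e-9))


# ---------------------------------------------------------------------------
# Spearman as Pearson of mid-ranks
# ---------------------------------------------------------------------------

def spearman_midrank_oracle(x, y) -> float:
    """Spearman rho computed longhand as Pearson on mid-ranks."""

    def midranks(v):
        v = np.asarray(v, float)
        out = np.empty(len(v))
        order = np.argsort(v, kind="mergesort")
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            out[order[i:j]] = (i + j + 1) / 2.0  # average of ranks i+1..j
            i = j
        return out

    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


# ---------------------------------------------------------------------------
# Dip statistic by linear programming over unimodal CDFs
# ---------------------------------------------------------------------------

def dip_lp_oracle(x) -> float:
    """Minimal sup-distance between the ECDF and any unimodal CDF.

    Searches every candidate mode location (each sample point, allowing an
    atom there, and each open interval between points) and solves a small
    linear program for the narrowest band ``d`` admitting a nondecreasing,
    convex-then-concave CDF through the band.  Exact up to LP tolerance;
    independent of the hull-based implementation it validates.
    """
    xs = np.sort(np.asarray(x, float))
    n = xs.size
    v, start = np.unique(xs, return_index=True)
    m = v.size
    if m == 1:
        return 0.5 / n
    a = start / n                                  # ECDF left limits
    b = np.append(start[1:], n) / n                # ECDF values

    best = np.inf
    for mode in range(m):
        best = min(best, _lp_mode_at_point(v, a, b, mode))
    for k in range(m - 1):
        best = min(best, _lp_mode_in_interval(v, a, b, k))
    return best


def _solve(c, a_ub, b_ub):
    res = linprog(c, A_ub=np.asarray(a_ub), b_ub=np.asarray(b_ub),
                  bounds=[(None, None)] * len(c), method="highs")
    return res.fun if res.status == 0 else np.inf


def _lp_mode_at_point(v, a, b, mode):
    """Band LP with the mode at v[mode]; the CDF may jump there."""
    m = len(v)
    # variables: g_0..g_{m-1} (g_mode = left limit), g_extra (value at mode), d
    n_var = m + 2
    extra, d = m, m + 1
    rows, rhs = [], []

    def le(coeffs, const):  # sum coeffs*z <= const
        row = np.zeros(n_var)
        for i, c in coeffs:
            row[i] += c
        rows.append(row)
        rhs.append(const)

    for j in range(m):
        if j == mode:
            le([(j, 1), (d, -1)], a[j])       # gL <= a + d
            le([(j, -1), (d, -1)], -a[j])     # gL >= a - d
            le([(extra, 1), (d, -1)], b[j])   # gR <= b + d
            le([(extra, -1), (d, -1)], -b[j])
        else:
            le([(j, 1), (d, -1)], a[j])       # g_j <= a_j + d
            le([(j, -1), (d, -1)], -b[j])     # g_j >= b_j - d
    # monotone: g_0 <= ... <= g_{m-1}, with gL <= gR inserted at the mode
    chain = list(range(mode + 1)) + [extra] + list(range(mode + 1, m))
    for u, w in zip(chain, chain[1:]):
        le([(u, 1), (w, -1)], 0.0)
    # convexity left of the mode (inclusive of the left limit at the mode)
    left = list(range(mode + 1))
    _add_shape(le, v, left, left, convex=True)
    # concavity from the mode value onward
    right = [extra] + list(range(mode + 1, m))
    xr = [v[mode]] + list(v[mode + 1:])
    _add_shape(le, xr, right, None, convex=False)

    c = np.zeros(n_var)
    c[d] = 1.0
    return _solve(c, rows, rhs)


def _lp_mode_in_interval(v, a, b, k):
    """Band LP with the mode strictly inside (v[k], v[k+1])."""
    m = len(v)
    n_var = m + 1
    d = m
    results = []
    # the bridging segment's slope must dominate the adjacent slope on at
    # least one side; try each side separately and keep the better LP
    for side in ("left", "right"):
        if side == "left" and k == 0:
            bridge = None
        elif side == "right" and k + 1 == m - 1:
            bridge = None
        else:
            bridge = side
        rows, rhs = [], []

        def le(coeffs, const, rows=rows, rhs=rhs):
            row = np.zeros(n_var)
            for i, c in coeffs:
                row[i] += c
            rows.append(row)
            rhs.append(const)

        for j in range(m):
            le([(j, 1), (d, -1)], a[j])
            le([(j, -1), (d, -1)], -b[j])
        for j in range(m - 1):
            le([(j, 1), (j + 1, -1)], 0.0)
        _add_shape(le, v, list(range(k + 1)), None, convex=True)
        _add_shape(le, v[k + 1:], list(range(k + 1, m)), None, convex=False)
        if bridge == "left":
            # slope(k -> k+1) >= slope(k-1 -> k)
            _slope_ge(le, v, k, k + 1, k - 1, k)
        elif bridge == "right":
            # slope(k -> k+1) >= slope(k+1 -> k+2)
            _slope_ge(le, v, k, k + 1, k + 1, k + 2)
        c = np.zeros(n_var)
        c[d] = 1.0
        results.append(_solve(c, rows, rhs))
        if bridge is None:
            break
    return min(results)


def _add_shape(le, xs, idx, _unused, convex: bool):
    """Increasing (convex) or decreasing (concave) slopes along idx."""
    xs = list(xs)
    for t in range(len(idx) - 2):
        i0, i1, i2 = idx[t], idx[t + 1], idx[t + 2]
        dx0 = xs[t + 1] - xs[t]
        dx1 = xs[t + 2] - xs[t + 1]
        # convex: (g2-g1)/dx1 >= (g1-g0)/dx0  <=>  (g1-g0)dx1 - (g2-g1)dx0 <= 0
        sgn = 1.0 if convex else -1.0
        le([(i0, -sgn * dx1), (i1, sgn * (dx1 + dx0)), (i2, -sgn * dx0)], 0.0)


def _slope_ge(le, v, a0, a1, b0, b1):
    """Constraint slope(a0->a1) >= slope(b0->b1)."""
    da = v[a1] - v[a0]
    db = v[b1] - v[b0]
    # (g_b1-g_b0)/db - (g_a1-g_a0)/da <= 0, cleared of denominators (da,db>0)
    le([(b1, da), (b0, -da), (a1, -db), (a0, db)], 0.0)
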