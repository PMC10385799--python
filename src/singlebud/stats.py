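"""Statistical primitives for single-bud expression analysis.

The module bundles the small set of tests and descriptive tools the
pipeline relies on: the Mann-Whitney U test for stage contrasts, Spearman
rank correlation for co-expression, Hartigan's dip statistic for
bimodality screening, upper Tukey fences for extreme-bud detection, and a
Gaussian kernel density estimate for distribution plots.

Mann-Whitney and Spearman delegate the numerics to :mod:`scipy.stats`
behind a stable interface that fixes the conventions used throughout the
package (two-sided p-values, mid-rank tie handling, t-approximation for
the Spearman p).  The dip statistic is implemented here in full because no
dependency provides it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "OutlierRule",
    "mann_whitney_u",
    "spearman",
    "spearman_matrix",
    "dip_statistic",
    "dip_null_table",
    "dip_test",
    "tukey_upper_outliers",
    "kde_density",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or one-sample test.

    ``statistic`` holds U for Mann-Whitney, rho for Spearman and D for the
    dip test.  ``method_detail`` records which computational path produced
    the p-value.
    """

    statistic: float
    p_value: float
    method_detail: Literal["exact", "approximate", "monte_carlo"]
    n_x: int
    n_y: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class OutlierRule:
    """Upper Tukey fence applied to one sample.

    The fence is ``q3 + k * iqr`` (or ``median + k * iqr`` when anchored at
    the median); indices whose value strictly exceeds the fence are
    flagged.  Only the upper side is screened: the phenomenon of interest
    is buds with unusually *high* expression.
    """

    k: float
    q1: float
    q3: float
    anchor: Literal["q3", "median"] = "q3"
    flagged: tuple[int, ...] = field(default_factory=tuple)

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def upper_fence(self) -> float:
        base = self.q3 if self.anchor == "q3" else self._median
        return base + self.k * self.iqr

    # populated at construction time by tukey_upper_outliers
    _median: float = float("nan")


def _as_1d(x: Sequence[float] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must not be empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

#: Largest sample size for which the exact null distribution is used when
#: the data carry no ties.  Mirrors the switch-over of R's ``wilcox.test``:
#: with the study's stage sizes, 10-vs-10 contrasts are exact while any
#: contrast against the 71-bud transition stage uses the tie-corrected
#: normal approximation with continuity correction.
EXACT_MAX_N = 49


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "normal_approx", "auto"] = "auto",
) -> TestResult:
    """Two-sided Mann-Whitney U test comparing two independent samples.

    ``mode='auto'`` selects the exact null distribution when both samples
    have at most :data:`EXACT_MAX_N` observations and no ties are present,
    and otherwise a tie-corrected normal approximation with continuity
    correction.
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    has_ties = np.unique(np.concatenate([xa, ya])).size < xa.size + ya.size
    if mode == "auto":
        use_exact = not has_ties and max(xa.size, ya.size) <= EXACT_MAX_N
    elif mode == "exact":
        if has_ties:
            raise ValueError("exact mode is undefined in the presence of ties")
        use_exact = True
    elif mode == "normal_approx":
        use_exact = False
    else:
        raise ValueError(f"unknown mode {mode!r}")

    res = sps.mannwhitneyu(
        xa, ya, alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method_detail="exact" if use_exact else "approximate",
        n_x=xa.size,
        n_y=ya.size,
    )


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _spearman_p_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via the t-approximation on n-2 df."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(rho) >= 1.0, 0.0, np.minimum(p, 1.0))


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    p_mode: Literal["approx", "exact"] = "approx",
) -> TestResult:
    """Spearman rank correlation with mid-rank tie handling.

    rho is the Pearson correlation of mid-ranks.  The p-value uses the
    classical t-approximation on ``n - 2`` degrees of freedom
    (``p_mode='approx'``) or, for n <= 8, exact enumeration of all rank
    permutations (``p_mode='exact'``).
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    n = xa.size
    if ya.size != n:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for constant input")

    rx = sps.rankdata(xa)
    ry = sps.rankdata(ya)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if p_mode == "approx":
        p = float(_spearman_p_from_rho(np.array(rho), n))
        return TestResult(rho, p, "approximate", n, n)
    if p_mode == "exact":
        if n > 8:
            raise ValueError("exact permutation p only supported for n <= 8")
        from itertools import permutations

        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += abs(r) >= target
            total += 1
        return TestResult(rho, count / total, "exact", n, n)
    raise ValueError(f"unknown p_mode {p_mode!r}")


def spearman_matrix(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided p for the columns of ``data``.

    Equivalent to calling :func:`spearman` on every column pair but
    vectorized; used by the resampling routines where thousands of
    correlation matrices are needed.  Columns with zero variance yield NaN
    rho/p against every other column.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a 2-D samples x variables array")
    n, _ = data.shape
    if n < 3:
        raise ValueError("need at least 3 rows")
    ranks = sps.rankdata(data, axis=0)
    sd = ranks.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho[np.isclose(sd, 0.0), :] = np.nan
    rho[:, np.isclose(sd, 0.0)] = np.nan
    p = _spearman_p_from_rho(rho, n)
    np.fill_diagonal(p, np.where(np.isnan(np.diag(rho)), np.nan, 0.0))
    return rho, p


# ---------------------------------------------------------------------------
# Hartigan's dip statistic
# ---------------------------------------------------------------------------

def _lower_hull(v: np.ndarray, y: np.ndarray, lo: int, hi: int) -> list[int]:
    """Touch indices of the greatest convex minorant of points (v_j, y_j)."""
    pts: list[int] = [lo]
    for j in range(lo + 1, hi + 1):
        while len(pts) >= 2:
            a, b = pts[-2], pts[-1]
            if (y[b] - y[a]) * (v[j] - v[a]) >= (y[j] - y[a]) * (v[b] - v[a]):
                pts.pop()
            else:
                break
        pts.append(j)
    return pts


def _upper_hull(v: np.ndarray, y: np.ndarray, lo: int, hi: int) -> list[int]:
    """Touch indices of the least concave majorant of points (v_j, y_j)."""
    pts: list[int] = [lo]
    for j in range(lo + 1, hi + 1):
        while len(pts) >= 2:
            a, b = pts[-2], pts[-1]
            if (y[b] - y[a]) * (v[j] - v[a]) <= (y[j] - y[a]) * (v[b] - v[a]):
                pts.pop()
            else:
                break
        pts.append(j)
    return pts


def dip_statistic(x: Sequence[float]) -> float:
    """Hartigan's dip statistic: the maximum distance between the empirical
    CDF and the closest unimodal CDF.

    The computation follows the classical iterative scheme: on the current
    modal interval, fit the greatest convex minorant (GCM) and least
    concave majorant (LCM) of the empirical CDF, measure the largest gap
    between the two fits, shrink the modal interval towards the gap and
    accumulate the deviations of the empirical CDF outside it.  Ties are
    handled through the left/right limits of the empirical CDF at each
    distinct value; a point mass at the mode itself costs nothing, as a
    unimodal distribution may carry an atom there.

    For any sample of ``n`` distinct values the statistic lies in
    ``[1/(2n), 1/4]``; the lower bound is attained by equally spaced data.
    """
    xs = np.sort(_as_1d(x, "x"))
    n = xs.size
    if n == 1 or xs[0] == xs[-1]:
        return 0.5 / n

    # collapse to distinct values; A = ECDF left limit counts, B = value counts
    v, start = np.unique(xs, return_index=True)
    a = start.astype(float)                        # counts just below v_j
    b = np.append(start[1:], n).astype(float)      # counts at v_j
    m = v.size

    lo, hi = 0, m - 1
    best = 1.0  # max deviation so far, in counts; 1 is the floor for any n>=2
    for _ in range(m + 2):
        gcm = _lower_hull(v, a, lo, hi)
        lcm = _upper_hull(v, b, lo, hi)
        union = np.union1d(gcm, lcm)
        gcm_vals = np.interp(v[union], v[gcm], a[gcm])
        lcm_vals = np.interp(v[union], v[lcm], b[lcm])
        gaps = lcm_vals - gcm_vals
        d = gaps.max()
        if d <= best:
            break
        p_star = int(union[int(np.argmax(gaps))])
        lcm_set = set(lcm)
        gcm_set = set(gcm)
        if p_star in lcm_set and p_star not in gcm_set:
            new_hi = p_star
            new_lo = max(g for g in gcm if g <= p_star)
        elif p_star in gcm_set and p_star not in lcm_set:
            new_lo = p_star
            new_hi = min(l for l in lcm if l >= p_star)
        else:  # touch point of both curves (tied data): collapse onto it
            new_lo = new_hi = p_star

        # deviations of the ECDF from the convex fit left of the modal
        # interval and from the concave fit right of it; at the interval
        # boundary itself only the approaching limit counts, because a
        # unimodal CDF may place an atom at its mode
        left = np.arange(lo, new_lo + 1)
        right = np.arange(new_hi, hi + 1)
        b_left = b[left].copy()
        b_left[-1] = a[new_lo]
        a_right = a[right].copy()
        a_right[0] = b[new_hi]
        dev_l = float(np.max(b_left - np.interp(v[left], v[gcm], a[gcm])))
        dev_u = float(np.max(np.interp(v[right], v[lcm], b[lcm]) - a_right))
        best = max(best, dev_l, dev_u)
        if (new_lo, new_hi) == (lo, hi):
            break
        lo, hi = new_lo, new_hi
    return best / (2.0 * n)


def dip_null_table(n: int, n_mc: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo null distribution of the dip for samples of size ``n``.

    Draws ``n_mc`` standard-uniform samples (the classical calibration
    null) and returns their dip statistics sorted ascending.  The table
    depends only on ``n``, so callers running many tests at a common
    sample size should compute it once and pass it to :func:`dip_test`.
    """
    dips = np.empty(n_mc)
    for i in range(n_mc):
        dips[i] = dip_statistic(rng.random(n))
    dips.sort()
    return dips


def dip_test(
    x: Sequence[float],
    n_mc: int = 10_000,
    rng: np.random.Generator | int | None = None,
    null_dips: np.ndarray | None = None,
) -> TestResult:
    """Hartigan's dip test of unimodality with a Monte-Carlo p-value.

    The p-value is the fraction of uniform(0, 1) samples of the same size
    whose dip is at least as large as the observed one.  A precomputed
    ``null_dips`` table (from :func:`dip_null_table`) bypasses the
    simulation.
    """
    xa = _as_1d(x, "x")
    n = xa.size
    if n < 4:
        raise ValueError("dip test needs at least 4 observations")
    d = dip_statistic(xa)
    if null_dips is None:
        if n_mc < 100:
            import warnings

            warnings.warn("n_mc < 100 gives a very coarse p-value", stacklevel=2)
        rng = np.random.default_rng(rng)
        null_dips = dip_null_table(n, n_mc, rng)
    else:
        null_dips = np.asarray(null_dips)
        n_mc = null_dips.size
    # null table is sorted: count entries >= d
    p = float(n_mc - np.searchsorted(null_dips, d, side="left")) / n_mc
    return TestResult(d, p, "monte_carlo", n)


# ---------------------------------------------------------------------------
# Tukey fences
# ---------------------------------------------------------------------------

def tukey_upper_outliers(
    x: Sequence[float],
    k: float = 3.0,
    anchor: Literal["q3", "median"] = "q3",
) -> OutlierRule:
    """Flag values strictly above the upper Tukey fence ``q3 + k * iqr``.

    Quartiles use linear interpolation of order statistics (the "type 7"
    convention, the default of both numpy and R), so the fence matches
    what an interactive analysis in either environment would report.
    ``anchor='median'`` replaces Q3 with the median as the fence base
    while keeping the IQR multiplier, a variant sometimes used for
    display.
    """
    xa = _as_1d(x, "x")
    if xa.size < 4:
        raise ValueError("need at least 4 observations to place a fence")
    if k < 0:
        raise ValueError("k must be nonnegative")
    q1, med, q3 = np.quantile(xa, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    base = q3 if anchor == "q3" else med
    fence = base + k * iqr
    flagged = tuple(int(i) for i in np.nonzero(xa > fence)[0])
    return OutlierRule(k=k, q1=float(q1), q3=float(q3), anchor=anchor,
                       flagged=flagged, _median=float(med))


# ---------------------------------------------------------------------------
# Kernel density
# ---------------------------------------------------------------------------

def kde_density(
    x: Sequence[float], n_grid: int = 512, cut: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density estimate on a regular grid.

    Bandwidth follows Silverman's rule as implemented by
    :class:`scipy.stats.gaussian_kde`; the grid extends ``cut`` bandwidths
    beyond the sample range so the trapezoid integral of the density is 1
    to well within 1e-3.
    """
    xa = _as_1d(x, "x")
    if xa.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(xa) == 0:
        raise ValueError("density undefined for a constant sample")
    kde = sps.gaussian_kde(xa, bw_method="silverman")
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(xa.min() - cut * h, xa.max() + cut * h, n_grid)
    return grid, kde(grid)
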