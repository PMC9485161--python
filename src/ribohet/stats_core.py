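"""Shared statistical kernel for the heterogeneity pipeline.

Every hypothesis test used by the analysis stages lives here and returns a
uniform :class:`TestResult`.  Standard tests (Welch's t, one-way ANOVA,
Spearman, Mann-Whitney, Fisher's exact, Benjamini-Hochberg) are routed
through scipy/statsmodels, with the degenerate-case conventions and the
exact/approximate routing handled explicitly so the contracts are pinned
regardless of library defaults.  Watson's two-sample U-squared for circular
data is implemented here directly, with permutation inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "welch_t",
    "one_way_anova",
    "spearman",
    "mann_whitney",
    "fisher_exact_2x2",
    "watson_u2",
    "bh_adjust",
    "ols_slope",
]


@dataclass
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    method: str
    statistic: float
    p_value: float
    sizes: tuple[int, ...]
    exact: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


def _as_float_array(x: Sequence[float], name: str, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise ValueError(f"{name}: need at least {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: non-finite values present")
    return arr


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided two-sample t test with unequal variances (Satterthwaite df).

    Degenerate conventions: if both groups have zero variance the test is
    decided by the means alone (P = 1 if equal, P = 0 otherwise).
    """
    xa = _as_float_array(x, "x", 2)
    ya = _as_float_array(y, "y", 2)
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if xa.mean() == ya.mean():
            return TestResult("welch_t", 0.0, 1.0, (xa.size, ya.size))
        return TestResult("welch_t", np.inf, 0.0, (xa.size, ya.size))
    t, p = sps.ttest_ind(xa, ya, equal_var=False)
    return TestResult("welch_t", float(t), float(p), (xa.size, ya.size))


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA on >=2 groups, unbalanced allowed.

    Degenerate conventions: SSB = SSW = 0 (all observations identical)
    gives P = 1; SSW = 0 with SSB > 0 gives P = 0.
    """
    arrs = [_as_float_array(g, f"group {i}", 1) for i, g in enumerate(groups)]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    n_total = sum(a.size for a in arrs)
    if n_total <= len(arrs):
        raise ValueError("need more observations than groups")
    grand = np.concatenate(arrs).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b = len(arrs) - 1
    df_w = n_total - len(arrs)
    sizes = tuple(a.size for a in arrs)
    if ssw == 0.0:
        if ssb == 0.0:
            return TestResult("one_way_anova", 0.0, 1.0, sizes,
                              extra={"df": (df_b, df_w)})
        return TestResult("one_way_anova", np.inf, 0.0, sizes,
                          extra={"df": (df_b, df_w)})
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult("one_way_anova", float(f), p, sizes,
                      extra={"df": (df_b, df_w)})


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks)."""
    xa = _as_float_array(x, "x", 2)
    ya = _as_float_array(y, "y", 2)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    rho = sps.spearmanr(xa, ya).statistic
    return float(rho)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test with average-rank tie handling.

    Uses the exact null distribution when min(n1, n2) <= 8 and there are no
    ties across the pooled sample; otherwise the normal approximation with
    tie and continuity corrections.  The reported U is that of the first
    sample (number of (x, y) pairs with x > y, ties counting 1/2).
    """
    xa = _as_float_array(x, "x", 1)
    ya = _as_float_array(y, "y", 1)
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (min(xa.size, ya.size) <= 8) and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue),
                      (xa.size, ya.size), exact=use_exact)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Fisher's exact test on a 2x2 contingency table.

    Two-sided P sums hypergeometric probabilities of all same-margin tables
    no more probable than the observed one.  A zero margin is degenerate
    (only one table possible): P = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must contain non-negative integers")
    n = int(t.sum())
    margins = [t[0].sum(), t[1].sum(), t[:, 0].sum(), t[:, 1].sum()]
    if n == 0 or any(m == 0 for m in margins):
        return TestResult("fisher_exact", np.nan, 1.0,
                          tuple(int(v) for v in t.ravel()), exact=True)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), float(p),
                      tuple(int(v) for v in t.ravel()), exact=True)


# Asymptotic critical values for the two-sample Watson U^2 statistic.
_WATSON_CRITICAL = {0.10: 0.152, 0.05: 0.187, 0.01: 0.268, 0.001: 0.385}


def _tie_block_index(values: np.ndarray) -> np.ndarray:
    """Index of the last element of each tie block, per position.

    ``values`` must be sorted ascending.  Evaluating both empirical CDFs at
    these indices makes tied observations share a single CDF step.
    """
    N = values.size
    block_end = np.empty(N, dtype=bool)
    block_end[:-1] = values[1:] != values[:-1]
    block_end[-1] = True
    ends = np.flatnonzero(block_end)
    return ends[np.searchsorted(ends, np.arange(N))]


def _watson_u2_statistic(values: np.ndarray, is_a: np.ndarray,
                         n: int, m: int) -> float:
    """U^2 from pooled sorted values and group-membership indicators."""
    N = n + m
    cum_a = np.cumsum(is_a)
    cum_b = np.arange(1, N + 1) - cum_a
    d = (cum_a / n - cum_b / m)[_tie_block_index(values)]
    return float((n * m / N**2) * (np.sum(d * d) - np.sum(d) ** 2 / N))


def watson_u2(angles_a: Sequence[float], angles_b: Sequence[float],
              n_perm: int = 9999, seed: int | None = None) -> TestResult:
    """Watson's two-sample U^2 test for circular data (degrees).

    The statistic is origin-invariant; P is estimated by random permutation
    of group labels with the add-one estimator (b + 1) / (n_perm + 1).
    Asymptotic critical values are reported in ``extra`` for reference.
    """
    a = np.mod(_as_float_array(angles_a, "angles_a", 8), 360.0)
    b = np.mod(_as_float_array(angles_b, "angles_b", 8), 360.0)
    n, m = a.size, b.size
    N = n + m
    pooled = np.concatenate([a, b])
    labels = np.zeros(N, dtype=np.int8)
    labels[:n] = 1
    order = np.argsort(pooled, kind="stable")
    values = pooled[order]

    obs = _watson_u2_statistic(values, labels[order] == 1, n, m)

    rng = np.random.default_rng(seed)
    # Permute labels over the fixed sorted pooled values: the values (and
    # hence the tie blocks) never change, only group membership does.
    tie_idx = _tie_block_index(values)
    ranks_arange = np.arange(1, N + 1)
    hits = 0
    done = 0
    while done < n_perm:
        bsz = min(256, n_perm - done)
        pos = np.argsort(rng.random((bsz, N)), axis=1)
        memb = np.zeros((bsz, N), dtype=np.int8)
        np.put_along_axis(memb, pos[:, :n], 1, axis=1)
        cum_a = np.cumsum(memb, axis=1)
        cum_b = ranks_arange[None, :] - cum_a
        d = (cum_a / n - cum_b / m)[:, tie_idx]
        stat = (n * m / N**2) * (np.sum(d * d, axis=1) - np.sum(d, axis=1) ** 2 / N)
        hits += int(np.sum(stat >= obs - 1e-12))
        done += bsz
    p = (hits + 1) / (n_perm + 1)
    return TestResult("watson_u2", obs, float(p), (n, m), exact=False,
                      extra={"critical_values": dict(_WATSON_CRITICAL),
                             "n_perm": n_perm})


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (monotone, order-stable)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ols_slope(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Ordinary least squares slope of y on x with a two-sided t test.

    Zero-residual fits report P = 0 for a nonzero slope and P = 1 for a
    zero slope (constant data).
    """
    xa = _as_float_array(x, "x", 3)
    ya = _as_float_array(y, "y", 3)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    sxx = np.sum((xa - xa.mean()) ** 2)
    if sxx == 0.0:
        raise ValueError("x has zero variance; slope undefined")
    slope = np.sum((xa - xa.mean()) * (ya - ya.mean())) / sxx
    intercept = ya.mean() - slope * xa.mean()
    resid = ya - (intercept + slope * xa)
    rss = float(np.sum(resid**2))
    df = n - 2
    scale = max(float(np.sum((ya - ya.mean()) ** 2)), 1.0)
    if rss <= 1e-24 * scale:
        p = 1.0 if slope == 0.0 else 0.0
        t = 0.0 if slope == 0.0 else np.inf
        return TestResult("ols_slope", float(slope), p, (n,),
                          extra={"t": t, "intercept": float(intercept)})
    se = np.sqrt(rss / df / sxx)
    t = slope / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult("ols_slope", float(slope), p, (n,),
                      extra={"t": float(t), "intercept": float(intercept),
                             "stderr": float(se)})
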