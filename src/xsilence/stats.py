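"""Exact nonparametric tests for small-sample group comparisons.

The Wilcoxon rank-sum test is computed by full enumeration of rank
assignments when the combined sample is small (ties handled with
mid-ranks), falling back to the tie-corrected normal approximation for
larger samples. Fisher's exact test enumerates all contingency tables
with the observed margins, defining two-sided extremeness by table
probability (tables at most as probable as the observed one), which
generalizes the standard 2x2 convention to r x c tables.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats as _sps

__all__ = ["rank_sum_test", "fisher_exact"]

_EXACT_MAX_N = 12
_REL_EPS = 1e-12


def _midranks(values: np.ndarray) -> np.ndarray:
    return _sps.rankdata(values, method="average")


def rank_sum_test(x, y, alternative: str = "two-sided"):
    """Wilcoxon rank-sum (Mann-Whitney U) test for two unpaired samples.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of *x*.
    For combined n <= 12 the p-value is exact, by enumeration of all
    C(n+m, n) assignments of the pooled mid-ranks; otherwise the normal
    approximation with tie correction is used (via scipy). The two-sided
    exact p counts assignments whose U deviates from its null mean at
    least as much as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)

    if n + m <= _EXACT_MAX_N:
        mu = n * m / 2.0
        total = math.comb(n + m, n)
        count = 0
        tol = _REL_EPS * (1 + abs(u_obs))
        for idx in combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - n * (n + 1) / 2
            if alternative == "two-sided":
                hit = abs(u - mu) >= abs(u_obs - mu) - tol
            elif alternative == "less":
                hit = u <= u_obs + tol
            else:
                hit = u >= u_obs - tol
            count += hit
        return u_obs, count / total

    res = _sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic",
                            use_continuity=False)
    return u_obs, float(res.pvalue)


def _log_fact(n: int) -> float:
    return math.lgamma(n + 1)


def _table_log_prob(table: np.ndarray) -> float:
    """Log conditional probability of an r x c table given its margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    lp = sum(_log_fact(int(r)) for r in rows) + sum(_log_fact(int(c)) for c in cols)
    lp -= _log_fact(n)
    lp -= sum(_log_fact(int(v)) for v in table.ravel())
    return lp


def _enumerate_tables(rows, cols):
    """Yield all non-negative integer tables with the given margins."""
    rows = list(rows)
    cols = list(cols)

    def rec(r_idx, remaining_cols, prefix):
        if r_idx == len(rows) - 1:
            yield prefix + [list(remaining_cols)]
            return
        target = rows[r_idx]

        def fill(c_idx, left, row):
            if c_idx == len(cols) - 1:
                if 0 <= left <= remaining_cols[c_idx]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[c_idx]) + 1):
                yield from fill(c_idx + 1, left - v, row + [v])

        for row in fill(0, target, []):
            new_cols = [rc - v for rc, v in zip(remaining_cols, row)]
            yield from rec(r_idx + 1, new_cols, prefix + [row])

    yield from rec(0, cols, [])


def fisher_exact(table) -> float:
    """Exact conditional test of independence for an r x c count table.

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of tables at most as probable as the
    observed one. For 2x2 tables this reproduces the classical two-sided
    Fisher exact p-value.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or obs.size == 0:
        raise ValueError("table must be a 2-D count array")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if obs.sum() == 0:
        raise ValueError("empty table")
    if not np.array_equal(obs, np.asarray(table, dtype=float)):
        raise ValueError("counts must be integers")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    lp_obs = _table_log_prob(obs)
    cutoff = lp_obs + _REL_EPS * (1 + abs(lp_obs))
    p = 0.0
    for cells in _enumerate_tables(rows, cols):
        t = np.asarray(cells, dtype=int)
        lp = _table_log_prob(t)
        if lp <= cutoff:
            p += math.exp(lp)
    return min(p, 1.0)
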