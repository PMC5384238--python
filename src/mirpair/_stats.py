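"""Shared exact-test and multiple-testing primitives.

These are the two statistical primitives every stage of the pipeline leans
on: the 2x2 Fisher exact test (conditional hypergeometric inference, with
both the right-tailed and the minimum-likelihood two-sided p-value) and the
Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "fisher_2x2",
    "odds_ratio",
    "haldane_odds_ratio",
    "bh_adjust",
]

# Relative tie tolerance (in log space) when summing outcomes "at most as
# probable" as the observed table; absorbs float noise in pmf evaluation.
_LOG_TIE_TOL = 1e-10


def odds_ratio(a: float, b: float, c: float, d: float) -> float:
    """Sample odds ratio ad/bc; +inf when bc == 0 < ad, NaN when ad == bc == 0."""
    if b * c == 0:
        return np.nan if a * d == 0 else np.inf
    return (a * d) / (b * c)


def haldane_odds_ratio(a: float, b: float, c: float, d: float) -> float:
    """Odds ratio with the Haldane-Anscombe 0.5 correction on every cell.

    Used only for *reporting/ranking* when a raw cell is zero; exact
    inference always uses the uncorrected table.
    """
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


def fisher_2x2(table) -> tuple[float, float, float]:
    """Exact inference for a 2x2 table ``[[a, b], [c, d]]``.

    Conditions on both margins: the top-left cell follows a hypergeometric
    distribution with population ``N = a+b+c+d``, ``a+b`` draws and ``a+c``
    successes.

    Returns
    -------
    (odds_ratio, p_right, p_two)
        Sample odds ratio ``ad/bc``; right-tailed p ``P(X >= a)``; two-sided
        p as the total probability of tables at most as probable as the one
        observed (no tail doubling).
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError(f"2x2 table cells must be non-negative integers, got {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return np.nan, 1.0, 1.0
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    k = np.arange(lo, hi + 1)
    # hypergeometric log pmf: C(c1, k) C(n - c1, r1 - k) / C(n, r1)
    logpmf = (_lchoose(c1, k) + _lchoose(n - c1, r1 - k) - _lchoose(n, r1))
    pmf = np.exp(logpmf - logpmf.max())
    total = pmf.sum()
    p_right = float(pmf[a - lo:].sum() / total)
    obs = logpmf[a - lo]
    keep = logpmf <= obs + _LOG_TIE_TOL
    p_two = float(pmf[keep].sum() / total)
    return odds_ratio(a, b, c, d), min(p_right, 1.0), min(p_two, 1.0)


def _lchoose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * n / j`` over the sorted p-values, clipped
    at 1; returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out
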