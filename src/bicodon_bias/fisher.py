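"""Two-sided Fisher exact test for 2x2 tables, in log space.

The table for a bicodon is ``[[o_L, syn_L - o_L], [o_H, syn_H - o_H]]`` where
``syn_X`` is the total count of the bicodon's synonymous group in sample X.
The two-sided p-value follows the minimum-likelihood convention: the sum of
hypergeometric probabilities of every table with the same margins whose
probability does not exceed the observed table's (a relative tolerance of
1e-7 on that comparison absorbs floating-point ties).

Log-factorials are evaluated exactly through the log-gamma function by
default; the ``stirling25`` mode instead applies Stirling's approximation
sqrt(2 pi n) (n/e)^n for n >= 25 and exact products below, reproducing the
historical approximation some analyses used.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
from scipy.special import gammaln

FactorialMode = Literal["lgamma", "stirling25"]

#: Relative tolerance when comparing table probabilities for two-siding.
REL_TOL = 1e-7
_LOG_REL_TOL = math.log1p(REL_TOL)

# exact log n! for n < 25 (Stirling mode switches at n = 25)
_SMALL_LOGFACT = np.array([math.lgamma(n + 1) for n in range(25)])


def log_factorial(n: np.ndarray | int, mode: FactorialMode = "lgamma") -> np.ndarray:
    """log(n!) elementwise, exact (log-gamma) or Stirling for n >= 25."""
    n = np.asarray(n, dtype=np.float64)
    if mode == "lgamma":
        return gammaln(n + 1.0)
    if mode != "stirling25":
        raise ValueError(f"unknown factorial mode: {mode!r}")
    n_safe = np.maximum(n, 1.0)
    stirling = 0.5 * np.log(2.0 * math.pi * n_safe) + n_safe * (np.log(n_safe) - 1.0)
    small = _SMALL_LOGFACT[np.minimum(n.astype(np.int64), 24)]
    return np.where(n < 25, small, stirling)


def _log_pmf_support(
    m1: int, syn_l: int, syn_h: int, mode: FactorialMode
) -> tuple[np.ndarray, np.ndarray]:
    """Support values a and log P(a) of the hypergeometric for given margins.

    ``a`` is the count in the (low sample, this bicodon) cell; ``m1`` the
    column margin o_L + o_H; the row margins are syn_l and syn_h.
    """
    n = syn_l + syn_h
    lo = max(0, m1 - syn_h)
    hi = min(m1, syn_l)
    a = np.arange(lo, hi + 1, dtype=np.int64)
    lf = lambda x: log_factorial(x, mode)  # noqa: E731
    log_pmf = (
        lf(syn_l) - lf(a) - lf(syn_l - a)
        + lf(syn_h) - lf(m1 - a) - lf(syn_h - (m1 - a))
        - (lf(n) - lf(m1) - lf(n - m1))
    )
    return a, log_pmf


def support_log_pvalues(
    m1: int, syn_l: int, syn_h: int, mode: FactorialMode = "lgamma"
) -> tuple[np.ndarray, np.ndarray]:
    """Natural-log two-sided p-value for every table sharing the margins.

    Probability mass is accumulated in log space, so extreme tails stay
    finite even where the linear p-value would underflow a double.
    """
    a, log_pmf = _log_pmf_support(m1, syn_l, syn_h, mode)
    order = np.argsort(log_pmf, kind="stable")
    sorted_lp = log_pmf[order]
    prefix = np.logaddexp.accumulate(sorted_lp)
    pos = np.searchsorted(sorted_lp, log_pmf + _LOG_REL_TOL, side="right")
    return a, np.minimum(prefix[pos - 1], 0.0)


def support_pvalues(
    m1: int, syn_l: int, syn_h: int, mode: FactorialMode = "lgamma"
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided p-value for every table sharing the margins.

    Returns ``(a_values, p_values)`` over the whole hypergeometric support;
    useful when many observed tables share margins (and for exhaustive
    verification).
    """
    a, log_p = support_log_pvalues(m1, syn_l, syn_h, mode)
    return a, np.exp(log_p)


def fisher_bicodon(
    o_l: int,
    o_h: int,
    syn_l: int,
    syn_h: int,
    factorial_mode: FactorialMode = "lgamma",
) -> float:
    """Two-sided Fisher exact p for one bicodon's 2x2 table."""
    if min(o_l, o_h, syn_l, syn_h) < 0:
        raise ValueError("counts must be non-negative")
    if o_l > syn_l or o_h > syn_h:
        raise ValueError("bicodon count exceeds its group total")
    if syn_l + syn_h == 0:
        return 1.0
    a, p = support_pvalues(o_l + o_h, syn_l, syn_h, factorial_mode)
    return float(p[o_l - a[0]])


def fisher_many(
    o_l: np.ndarray,
    o_h: np.ndarray,
    syn_l: np.ndarray,
    syn_h: np.ndarray,
    factorial_mode: FactorialMode = "lgamma",
) -> np.ndarray:
    """Vector of two-sided Fisher p-values, caching shared margins."""
    o_l = np.asarray(o_l)
    o_h = np.asarray(o_h)
    syn_l = np.asarray(syn_l)
    syn_h = np.asarray(syn_h)
    out = np.ones(o_l.shape, dtype=float)
    cache: dict[tuple[int, int, int], tuple[int, np.ndarray]] = {}
    for i in range(o_l.size):
        key = (int(o_l[i] + o_h[i]), int(syn_l[i]), int(syn_h[i]))
        if key[1] + key[2] == 0:
            continue
        hit = cache.get(key)
        if hit is None:
            a, p = support_pvalues(*key, mode=factorial_mode)
            hit = (int(a[0]), p)
            cache[key] = hit
        lo, p = hit
        out[i] = p[int(o_l[i]) - lo]
    return out
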