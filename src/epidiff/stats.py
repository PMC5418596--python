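"""Shared statistical primitives: exact Fisher test, BH FDR, rounding.

The two-sided Fisher's exact p-value is the sum of hypergeometric
probabilities, over all 2x2 tables with the observed margins, that do not
exceed the probability of the observed table.  For small tables the sum is
computed with exact integer arithmetic (binomial-coefficient weights over a
common denominator), so that ties between table probabilities — which are
ties between integers — are classified exactly.  Large tables (as arise
when testing one locus against the rest of a sequencing library) fall back
to :func:`scipy.stats.fisher_exact`.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from functools import lru_cache
from itertools import accumulate

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_exact_two_sided",
    "benjamini_hochberg",
    "round_counts",
    "proportion_ztest_two_sided",
]

#: largest table total handled by the exact integer path
_EXACT_TOTAL = 2000


@lru_cache(maxsize=1 << 18)
def _hypergeom_weights(r1: int, r2: int, c1: int):
    """Integer table weights C(r1,x)*C(r2,c1-x) over the support of x,
    plus sorted weights with cumulative sums and the common denominator."""
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = tuple(math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1))
    ordered = sorted(weights)
    cums = tuple(accumulate(ordered))
    total = math.comb(r1 + r2, c1)
    return lo, weights, tuple(ordered), cums, total


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the 2x2 table [[a, b], [c, d]].

    Returns the sum of probabilities of all tables with the same margins
    whose probability does not exceed that of the observed table.  The
    all-zero table returns 1 by convention.
    """
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    if n <= _EXACT_TOTAL:
        lo, weights, ordered, cums, total = _hypergeom_weights(a + b, c + d, a + c)
        w_obs = weights[a - lo]
        idx = bisect_right(ordered, w_obs)
        return cums[idx - 1] / total
    p = float(_sps.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    return min(p, 1.0)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def round_counts(x):
    """Centralized rounding of smoothed read counts before exact testing.

    Half-integers round to the nearest even integer (the convention of
    ``round()`` in R, where the original statistics were computed).
    """
    return np.rint(x)


def proportion_ztest_two_sided(observed: int, n: int, p0: float):
    """One-sample two-sided z-test of a proportion against ``p0``.

    z = (p_hat - p0) / sqrt(p0 (1 - p0) / n); the p-value comes from the
    normal approximation.  Returns ``(z, p)``.
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    if not 0.0 < p0 < 1.0:
        raise ValueError("background proportion must lie strictly in (0, 1)")
    phat = observed / n
    z = (phat - p0) / math.sqrt(p0 * (1.0 - p0) / n)
    p = 2.0 * _sps.norm.sf(abs(z))
    return z, min(p, 1.0)
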