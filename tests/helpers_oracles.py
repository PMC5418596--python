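"""Independent brute-force oracles used by the test suite.

Each oracle re-derives the quantity from its definition by direct
enumeration or naive computation, deliberately sharing no code with the
package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def local_quadratic_fit_oracle(values, window=11, degree=2, clamp=True):
    """Per-position local least-squares polynomial fit over the window of
    index-adjacent values, truncated at the ends, evaluated at the centre;
    clamped at zero from below."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        deg = min(degree, hi - lo - 1)
        t = np.arange(lo, hi) - i
        # normal equations of the naive polynomial regression
        design = np.column_stack([t.astype(float) ** k for k in range(deg + 1)])
        coef = np.linalg.solve(design.T @ design, design.T @ x[lo:hi])
        out[i] = coef[0]
    if clamp:
        out = np.maximum(out, 0.0)
    return out


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration with exact
    integer arithmetic: sum of P(tables) whose probability <= P(observed),
    margins fixed."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    total = math.comb(n, c1)
    return sum(v for v in nums if v <= obs) / total


def bh_oracle(pvalues):
    """Step-up BH from the definition: q_(i) = min_{j>=i} m p_(j)/j, cap 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def merge_oracle(positions, types, max_gap):
    """Region construction by explicit link enumeration + union-find.

    A link joins two *consecutive same-type* DMCs (adjacent in the
    same-type subsequence) when their distance is <= max_gap and no
    opposite-type DMC lies strictly between them.  Returns a sorted list
    of (start, end, type, n_dmcs).
    """
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for typ in set(types):
        idx = [i for i in range(n) if types[i] == typ]
        for a, b in zip(idx, idx[1:]):
            if positions[b] - positions[a] > max_gap:
                continue
            blocked = any(
                types[k] != typ and positions[a] < positions[k] < positions[b]
                for k in range(n)
            )
            if not blocked:
                union(a, b)

    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    regions = []
    for members in groups.values():
        pos = [positions[i] for i in members]
        regions.append((min(pos), max(pos), types[members[0]], len(members)))
    return sorted(regions)


def interval_overlap_oracle(a_start, a_end, b_start, b_end):
    """Per-base intersection of two 1-based inclusive intervals."""
    bases = set(range(a_start, a_end + 1)) & set(range(b_start, b_end + 1))
    return len(bases) > 0


def windowed_log2_oracle(loci, rpkm_wt, rpkm_mut, chrom, size, window):
    """Naive per-window recomputation of the mean-RPKM log2 ratio track."""
    out = []
    n_win = int(np.ceil(size / window))
    for w in range(n_win):
        lo, hi = w * window + 1, min((w + 1) * window, size)
        vals_wt, vals_mut = [], []
        for i, row in loci.iterrows():
            if row["chrom"] != chrom:
                continue
            mid = (row["start"] + row["end"]) // 2
            if lo <= mid <= hi:
                vals_wt.append(rpkm_wt[i])
                vals_mut.append(rpkm_mut[i])
        if vals_wt and np.mean(vals_wt) > 0 and np.mean(vals_mut) > 0:
            out.append(float(np.log2(np.mean(vals_mut) / np.mean(vals_wt))))
        else:
            out.append(float("nan"))
    return out


def scaled_profile_oracle(cov_vec, length, flank, body_bins):
    """Brute-force bin mapping for one plus-strand TE.

    ``cov_vec`` covers [start-flank, end+flank] per bp.  Returns an array
    of 2*flank + body_bins values (NaN where no position maps)."""
    total = 2 * flank + body_bins
    out = np.full(total, np.nan)
    out[:flank] = cov_vec[:flank]
    out[flank + body_bins:] = cov_vec[flank + length:]
    sums = {}
    for j in range(length):
        b = min(int(j * body_bins // length), body_bins - 1)
        sums.setdefault(b, []).append(cov_vec[flank + j])
    for b, vals in sums.items():
        out[flank + b] = np.mean(vals)
    return out
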