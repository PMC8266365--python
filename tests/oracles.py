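"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: interval arithmetic is
done on per-bp boolean bitmaps, rank/contingency tests by exhaustive
enumeration, and BH by its step-up definition applied literally.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def bitmap(intervals, genome):
    """Per-bp boolean coverage arrays keyed by chromosome."""
    arrays = {c: np.zeros(int(s), dtype=bool) for c, s in genome.items()}
    for chrom, start, end, *_ in intervals:
        arrays[chrom][start:end] = True
    return arrays


def bitmap_union_bp(intervals, genome):
    return sum(a.sum() for a in bitmap(intervals, genome).values())


def bitmap_overlap_bp(a, b, genome):
    ba, bb = bitmap(a, genome), bitmap(b, genome)
    return sum((ba[c] & bb[c]).sum() for c in genome)


def brute_force_near(points, intervals, window):
    out = []
    for chrom, pos in points:
        hit = any(
            c == chrom and s - window <= pos < e + window
            for c, s, e, *_ in intervals
        )
        out.append(hit)
    return np.array(out)


def bh_textbook(pvals):
    """Step-up BH from the definition: adjusted p_(i) = min over j>=i of
    min(1, m*p_(j)/j)."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    for rank_i in range(m):
        candidates = [
            min(1.0, m * p[order[j]] / (j + 1)) for j in range(rank_i, m)
        ]
        adj_sorted[rank_i] = min(candidates)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def hypergeom_upper_tail_exact(N, K, n, k):
    """P(X >= k) for X ~ Hypergeom(N, K, n) via exact rational summation."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)


def mann_whitney_u_bruteforce(a, b):
    """U statistic for sample a by direct pair counting (ties count 1/2)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mann_whitney_exact_p(a, b):
    """Two-sided exact p by enumerating all group assignments of the pooled
    sample (small n only)."""
    pooled = list(a) + list(b)
    n_a = len(a)
    observed = mann_whitney_u_bruteforce(a, b)
    mu = n_a * len(b) / 2.0
    count = 0
    total = 0
    idx = range(len(pooled))
    for grp in combinations(idx, n_a):
        ga = [pooled[i] for i in grp]
        gb = [pooled[i] for i in idx if i not in grp]
        u = mann_whitney_u_bruteforce(ga, gb)
        if abs(u - mu) >= abs(observed - mu) - 1e-12:
            count += 1
        total += 1
    return count / total
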