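"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: the overlap oracle is
a vectorized all-pairs computation straight from the arithmetic definition,
and the hypergeometric oracle uses exact rational arithmetic over binomial
coefficients.
"""

from fractions import Fraction
from math import comb

import numpy as np


def overlap_matrix(starts_a, ends_a, starts_b, ends_b, min_frac=0.5,
                   mode="either"):
    """Boolean all-pairs matrix of the fractional-overlap rule.

    All intervals are assumed to lie on one chromosome; multi-chromosome
    instances are handled by calling this per chromosome.
    """
    sa = np.asarray(starts_a)[:, None]
    ea = np.asarray(ends_a)[:, None]
    sb = np.asarray(starts_b)[None, :]
    eb = np.asarray(ends_b)[None, :]
    ovl = np.maximum(0, np.minimum(ea, eb) - np.maximum(sa, sb))
    over_a = ovl > min_frac * (ea - sa)
    over_b = ovl > min_frac * (eb - sb)
    return (over_a | over_b) if mode == "either" else (over_a & over_b)


def brute_force_shared_flags(ivs_a, ivs_b, min_frac=0.5, mode="either"):
    """For each interval of A, whether it overlaps any interval of B.

    ``ivs_*`` are sequences of (chrom, start, end) triples.
    """
    flags = np.zeros(len(ivs_a), dtype=bool)
    chroms = sorted({c for c, _, _ in ivs_a} | {c for c, _, _ in ivs_b})
    idx_a = {c: [i for i, (cc, _, _) in enumerate(ivs_a) if cc == c]
             for c in chroms}
    idx_b = {c: [i for i, (cc, _, _) in enumerate(ivs_b) if cc == c]
             for c in chroms}
    for c in chroms:
        ia, ib = idx_a[c], idx_b[c]
        if not ia or not ib:
            continue
        mat = overlap_matrix(
            [ivs_a[i][1] for i in ia], [ivs_a[i][2] for i in ia],
            [ivs_b[j][1] for j in ib], [ivs_b[j][2] for j in ib],
            min_frac, mode,
        )
        flags[np.asarray(ia)] = mat.any(axis=1)
    return flags


def exact_hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) as an exact rational from the combinatorial definition."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(max(k, 0), min(n, K) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def bh_step_up(p_values):
    """Benjamini-Hochberg adjusted p-values by the textbook step-up rule."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, p[i] * m / (pos + 1))
        adjusted[i] = running_min
    return adjusted
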