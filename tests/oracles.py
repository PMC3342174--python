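"""Independent brute-force oracles used only by the test suite.

These deliberately avoid scipy's test implementations: the rank-sum
oracle enumerates all assignments of the pooled ranks to the first
sample, and the Fisher oracle sums exact rational hypergeometric
probabilities over all tables with the observed margins.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def rank_sum_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration (no ties).

    Two-sidedness uses the symmetry of the null U distribution:
    p = P(|U - n1 n2 / 2| >= |u_obs - n1 n2 / 2|).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires no ties"
    n1, n2 = len(a), len(b)
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * n2 / 2
    hits = 0
    total = comb(n1 + n2, n1)
    all_ranks = range(1, n1 + n2 + 1)
    for subset in combinations(all_ranks, n1):
        u = sum(subset) - n1 * (n1 + 1) / 2
        if abs(u - center) >= abs(u_obs - center) - 1e-9:
            hits += 1
    return hits / total


def fisher_exact_p(table) -> float:
    """Two-sided Fisher p by exact rational enumeration over all 2x2
    tables with the observed margins (probability <= observed)."""
    (a, b), (c, d) = [list(map(int, row)) for row in np.asarray(table)]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return float(sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs))
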