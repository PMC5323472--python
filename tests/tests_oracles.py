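"""Brute-force statistical oracles, independent of the implementations
they check (enumeration over hypergeometric tables / rank assignments)."""

import itertools

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided_oracle(table):
    """Two-sided Fisher exact p by exhaustive enumeration over all 2x2
    tables with the observed margins."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for a_alt in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = hypergeom.pmf(a_alt, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def mannwhitney_two_sided_oracle(a, b):
    """Exact two-sided Mann-Whitney p by enumeration of all group
    assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_stat(x, y):
        return sum(1 for i in x for j in y if i > j) + 0.5 * sum(
            1 for i in x for j in y if i == j
        )

    u_obs = u_stat(a, b)
    mid = n1 * len(b) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        sel = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        total += 1
        if abs(u_stat(sel, rest) - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
    return count / total
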