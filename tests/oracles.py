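"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: combinatorial
enumeration with exact integer arithmetic, and textbook sums-of-squares.
"""

import math

import numpy as np


def hypergeom_tail_oracle(a: int, k_regulon: int, n_deg: int,
                          n_total: int) -> float:
    """Upper-tail hypergeometric mass P(X >= a) by exact enumeration."""
    total = math.comb(n_total, n_deg)
    return sum(
        math.comb(k_regulon, x) * math.comb(n_total - k_regulon, n_deg - x)
        for x in range(a, min(k_regulon, n_deg) + 1)
    ) / total


def anova_f_oracle(groups: list[np.ndarray]) -> float:
    """One-way fixed-effects F by explicit sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ssb / df_b) / (ssw / df_w)
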