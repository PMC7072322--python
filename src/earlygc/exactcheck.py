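"""Independent brute-force references for the exact statistics.

These routines re-derive the package's inferential primitives from first
principles — exhaustive hypergeometric enumeration with exact integer
arithmetic for the Fisher test, and the literal step-up formula for
Benjamini–Hochberg — so the production code paths (SciPy / statsmodels)
can be validated against an implementation that shares nothing with them.
They are deliberately simple and unoptimized.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np


def fisher_exact_enum(
    table: Sequence[Sequence[int]], alternative: str = "two-sided"
) -> float:
    """Fisher exact p by full enumeration of the hypergeometric support.

    For fixed margins the table is determined by its top-left cell k; each
    k is weighted w(k) = C(r1, k) * C(r2, c1 - k). One-sided tails sum
    k >= a (greater) or k <= a (less); the two-sided p sums every k whose
    probability does not exceed the observed table's (exact integer
    comparison). All arithmetic is exact until the final division.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    k_min, k_max = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(k_min, k_max + 1)}
    total = comb(n, c1)
    if alternative == "greater":
        num = sum(w for k, w in weights.items() if k >= a)
    elif alternative == "less":
        num = sum(w for k, w in weights.items() if k <= a)
    elif alternative == "two-sided":
        w_obs = weights[a]
        num = sum(w for w in weights.values() if w <= w_obs)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(Fraction(num, total))


def bh_stepup(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg q-values by the literal step-up formula.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at
    1, mapped back to the input order; ties receive equal q.
    """
    p = np.asarray(list(p_values), dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
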