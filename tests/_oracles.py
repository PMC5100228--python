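"""Independent arbitrary-precision oracles used by the test suite.

Everything here is exact rational arithmetic (fractions + integer
binomials), deliberately sharing no code path with the package's
log-space / special-function implementations.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def ac_pmf_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """p(y|x) = (n2/n1)^y (x+y)! / (x! y! (1+n2/n1)^(x+y+1)), exactly."""
    r = Fraction(n2, n1)
    return comb(x + y, y) * r**y / (1 + r) ** (x + y + 1)


def ac_two_sided_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Two-sided doubling of the smaller tail of S = sum_{i<=y} p(i|x)."""
    s = sum(ac_pmf_exact(x, i, n1, n2) for i in range(y + 1))
    p = 2 * s if s <= Fraction(1, 2) else 2 * (1 - s)
    return min(max(p, Fraction(0)), Fraction(1))


def hypergeom_upper_exact(N: int, n: int, M: int, m: int) -> Fraction:
    """P(X >= m) for X hypergeometric(N, M, n), by direct enumeration."""
    if m == 0:
        return Fraction(1)
    denom = comb(N, n)
    acc = Fraction(0)
    for i in range(m):
        a = comb(M, i) if i <= M else 0
        b = comb(N - M, n - i) if 0 <= n - i <= N - M else 0
        acc += Fraction(a * b, denom)
    return 1 - acc


def bh_stepup_exact(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up by its definition, in input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [min(1.0, m * pvals[order[i]] / (i + 1)) for i in range(m)]
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = q_sorted[rank]
    return out
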