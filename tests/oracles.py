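"""Independent exact-arithmetic oracles used across the test suite.

The hypergeometric oracle works entirely in rational arithmetic
(``fractions.Fraction`` over exact integer binomial coefficients), so its
values are mathematically exact; floats enter only at the final comparison.
It deliberately shares no code with the implementation under test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def exact_pmf(N: int, K: int, n: int, k: int) -> Fraction:
    """P[X = k] as an exact rational."""
    return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))


def exact_support(N: int, K: int, n: int) -> range:
    return range(max(0, n + K - N), min(K, n) + 1)


def exact_upper(N: int, K: int, n: int, k: int) -> Fraction:
    """P[X >= k] as an exact rational."""
    return sum(
        (exact_pmf(N, K, n, j) for j in exact_support(N, K, n) if j >= k),
        Fraction(0),
    )


def exact_lower(N: int, K: int, n: int, k: int) -> Fraction:
    """P[X <= k] as an exact rational."""
    return sum(
        (exact_pmf(N, K, n, j) for j in exact_support(N, K, n) if j <= k),
        Fraction(0),
    )
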