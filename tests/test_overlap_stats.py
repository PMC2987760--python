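"""Exact hypergeometric machinery and the directional overlap test.

Two independent oracles back these tests: exact rational arithmetic
(``oracles.py``) and scipy's hypergeometric distribution. The implementation
under test never touches either.
"""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from countersig import (
    Call,
    DirectionalSignature,
    GeneSet,
    OverlapCounts,
    UndefinedTestError,
    directional_overlap_test,
    hypergeom_lower,
    hypergeom_pmf,
    hypergeom_upper,
    log_binomial,
    overlap_test,
)
from oracles import exact_lower, exact_pmf, exact_upper


@st.composite
def overlap_counts(draw, max_n=200, min_n=0):
    N = draw(st.integers(min_n, max_n))
    K = draw(st.integers(0, N))
    n = draw(st.integers(0, N))
    k = draw(st.integers(max(0, n + K - N), min(K, n)))
    return OverlapCounts(N, K, n, k)


class TestLogBinomial:
    def test_small_values_exact(self):
        assert log_binomial(4, 2) == pytest.approx(math.log(6), abs=1e-14)
        assert log_binomial(10, 0) == 0.0
        assert log_binomial(10, 10) == 0.0

    def test_against_exact_integer_coefficient(self):
        exact = math.comb(50, 25)
        assert log_binomial(50, 25) == pytest.approx(math.log(exact), rel=1e-13)

    @pytest.mark.parametrize("n,k", [(5, 6), (-1, 0), (3, -2)])
    def test_domain_errors(self, n, k):
        with pytest.raises(ValueError):
            log_binomial(n, k)

    @given(st.integers(0, 2000), st.data())
    @settings(max_examples=100, derandomize=True)
    def test_symmetry(self, n, data):
        k = data.draw(st.integers(0, n))
        assert log_binomial(n, k) == pytest.approx(log_binomial(n, n - k), rel=1e-12, abs=1e-12)


class TestOverlapCounts:
    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            OverlapCounts(10, 11, 5, 3)  # K > N
        with pytest.raises(ValueError):
            OverlapCounts(10, 4, 5, 5)  # k > min(K, n)
        with pytest.raises(ValueError):
            OverlapCounts(10, 8, 9, 5)  # k below max(0, n + K - N) = 7


class TestHypergeomProbabilities:
    def test_tiny_enumeration(self):
        # C(2,1)C(2,1)/C(4,2) = 4/6
        assert hypergeom_pmf(OverlapCounts(4, 2, 2, 1)) == pytest.approx(2 / 3, abs=1e-14)

    def test_upper_tail_at_support_min_is_one(self):
        assert hypergeom_upper(OverlapCounts(100, 30, 20, 0)) == 1.0

    def test_lower_tail_at_support_max_is_one(self):
        assert hypergeom_lower(OverlapCounts(100, 30, 20, 20)) == 1.0

    def test_upper_by_direct_pmf_summation(self):
        c = OverlapCounts(419, 9, 41, 3)
        oracle = sum(
            float(exact_pmf(419, 9, 41, j)) for j in range(3, 10)
        )
        assert hypergeom_upper(c) == pytest.approx(oracle, rel=1e-12)
        assert hypergeom_upper(c) == pytest.approx(0.0482, abs=5e-5)

    def test_lower_by_complement_identity(self):
        c = OverlapCounts(10, 4, 3, 1)
        complement = 1.0 - hypergeom_upper(OverlapCounts(10, 4, 3, 2))
        assert hypergeom_lower(c) == pytest.approx(complement, abs=1e-14)

    @given(overlap_counts())
    @settings(max_examples=200, derandomize=True)
    def test_pmf_normalizes_over_support(self, c):
        total = math.fsum(
            hypergeom_pmf(OverlapCounts(c.N, c.K, c.n, k))
            for k in range(c.support_min, c.support_max + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    @given(overlap_counts())
    @settings(max_examples=200, derandomize=True)
    def test_category_sample_symmetry(self, c):
        swapped = OverlapCounts(c.N, c.n, c.K, c.k)
        assert hypergeom_pmf(c) == pytest.approx(hypergeom_pmf(swapped), rel=1e-12, abs=1e-300)
        assert hypergeom_upper(c) == pytest.approx(hypergeom_upper(swapped), rel=1e-12)
        assert hypergeom_lower(c) == pytest.approx(hypergeom_lower(swapped), rel=1e-12)

    @given(overlap_counts())
    @settings(max_examples=200, derandomize=True)
    def test_tail_point_identity(self, c):
        assert hypergeom_upper(c) + hypergeom_lower(c) - hypergeom_pmf(c) == pytest.approx(
            1.0, abs=1e-12
        )

    @given(overlap_counts(max_n=500, min_n=1))  # scipy's pmf is undefined at N=0
    @settings(max_examples=100, derandomize=True)
    def test_agrees_with_scipy(self, c):
        dist = hypergeom(c.N, c.K, c.n)
        assert hypergeom_pmf(c) == pytest.approx(float(dist.pmf(c.k)), rel=1e-9, abs=1e-12)
        assert hypergeom_upper(c) == pytest.approx(float(dist.sf(c.k - 1)), rel=1e-9, abs=1e-12)
        assert hypergeom_lower(c) == pytest.approx(float(dist.cdf(c.k)), rel=1e-9, abs=1e-12)

    def test_upper_strictly_decreasing_in_k(self):
        c0 = OverlapCounts(80, 30, 25, 0)
        values = [
            hypergeom_upper(OverlapCounts(80, 30, 25, k))
            for k in range(c0.support_min, c0.support_max + 1)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_exhaustive_exact_rational_equivalence_small_universes(self):
        """Float implementation equals exact rational arithmetic for all N <= 60."""
        for N in range(0, 61):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    lo, hi = max(0, n + K - N), min(K, n)
                    denom = math.comb(N, n)
                    running = 0
                    pmf_nums = [
                        math.comb(K, k) * math.comb(N - K, n - k)
                        for k in range(lo, hi + 1)
                    ]
                    total = sum(pmf_nums)
                    assert total == denom  # Vandermonde, sanity on the oracle
                    for idx, k in enumerate(range(lo, hi + 1)):
                        running += pmf_nums[idx]
                        c = OverlapCounts(N, K, n, k)
                        assert hypergeom_pmf(c) == pytest.approx(
                            float(Fraction(pmf_nums[idx], denom)), rel=1e-11, abs=1e-15
                        )
                        assert hypergeom_lower(c) == pytest.approx(
                            float(Fraction(running, denom)), rel=1e-11
                        )
                        assert hypergeom_upper(c) == pytest.approx(
                            float(Fraction(total - running + pmf_nums[idx], denom)),
                            rel=1e-11,
                        )


def _sig(up, down):
    return DirectionalSignature(
        "pool",
        GeneSet("up", "human", frozenset(up)),
        GeneSet("down", "human", frozenset(down)),
    )


class TestDirectionalOverlapTest:
    def test_published_counts_called_enriched_and_depleted(self, planted_bundle):
        up_test, down_test = directional_overlap_test(
            planted_bundle.pooled, planted_bundle.drug_mapped, alpha=0.05
        )
        assert (up_test.counts.N, up_test.counts.K, up_test.counts.n, up_test.counts.k) == (
            716, 419, 56, 41,
        )
        assert (down_test.counts.K, down_test.counts.k) == (301, 16)
        assert up_test.call is Call.ENRICHED and up_test.p_upper < 0.05
        assert down_test.call is Call.DEPLETED and down_test.p_lower < 0.05

    def test_disjoint_drug_is_neutral_with_p_one(self):
        pooled = _sig({"A", "B", "C"}, {"D", "E"})
        drug = GeneSet("drug", "human", frozenset({"X", "Y"}))
        up_test, down_test = directional_overlap_test(pooled, drug)
        for t in (up_test, down_test):
            assert t.p_point == t.p_upper == t.p_lower == 1.0
            assert t.call is Call.NEUTRAL

    def test_tiny_instance_enumeration(self):
        # universe 6, up/down disjoint triples, drug = the up set:
        # P[X >= 3] = C(3,3)C(3,0)/C(6,3) = 1/20
        pooled = _sig({"A", "B", "C"}, {"D", "E", "F"})
        drug = GeneSet("drug", "human", frozenset({"A", "B", "C"}))
        up_test, _ = directional_overlap_test(pooled, drug)
        assert up_test.counts.k == 3
        assert up_test.p_upper == pytest.approx(1 / 20, abs=1e-14)

    def test_empty_universe_rejected(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pooled = _sig(set(), set())
        with pytest.raises(UndefinedTestError):
            directional_overlap_test(pooled, GeneSet("d", "human", frozenset({"A"})))

    def test_result_probabilities_consistent(self):
        r = overlap_test(OverlapCounts(716, 419, 56, 41))
        assert 0.0 <= r.p_point <= 1.0
        assert r.p_upper + r.p_lower - r.p_point == pytest.approx(1.0, abs=1e-12)
        assert r.expected == pytest.approx(56 * 419 / 716)
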