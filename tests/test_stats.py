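"""Statistical kernel versus independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lohsel import stats


def chisq_2x2_formula(a, b, c, d):
    """Textbook Pearson formula: sum (O-E)^2/E over the four cells."""
    n = a + b + c + d
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    obs = ((a, b), (c, d))
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (obs[i][j] - e) ** 2 / e
    return stat


def binom_two_sided_enum(k, n, p0):
    """Full-enumeration minlike two-sided binomial p-value.

    Sums P(X = i) over all outcomes whose point probability does not
    exceed that of the observed outcome, with the conventional 1e-7
    relative tolerance for ties.
    """
    probs = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    cut = probs[k] * (1 + 1e-7)
    return min(1.0, sum(p for p in probs if p <= cut))


class TestChisqGof2:
    @pytest.mark.parametrize(
        "a,b,expected_p",
        [
            (22, 6, 0.0025),  # directional allele loss
            (44, 44, 1.0000),  # perfectly symmetric
            (1, 9, 0.0114),
            (70, 48, 0.0428),
            (7, 22, 0.0053),
            (4, 15, 0.0116),
        ],
    )
    def test_published_benchmark_splits(self, a, b, expected_p):
        res = stats.chisq_gof_2(a, b)
        assert res.df == 1
        assert round(res.p_value, 4) == expected_p

    def test_uncorrected_statistic(self):
        # 22 vs 6: (22-14)^2/14 + (6-14)^2/14 = 128/14
        assert stats.chisq_gof_2(22, 6).statistic == pytest.approx(128 / 14)

    def test_both_zero_is_degenerate(self):
        with pytest.raises(stats.DegenerateInputError):
            stats.chisq_gof_2(0, 0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 500), st.integers(0, 500))
    def test_symmetry(self, a, b):
        if a + b == 0:
            return
        r1 = stats.chisq_gof_2(a, b)
        r2 = stats.chisq_gof_2(b, a)
        assert r1.p_value == r2.p_value
        assert r1.statistic == r2.statistic

    def test_p_monotone_in_imbalance(self):
        total = 60
        ps = [stats.chisq_gof_2(total // 2 + d, total // 2 - d).p_value for d in range(0, 30)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


class TestChisq2x2:
    def test_independent_table(self):
        assert stats.chisq_2x2(10, 10, 10, 10).p_value == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        res = stats.chisq_2x2(50, 10, 10, 50)
        assert res.statistic == pytest.approx(chisq_2x2_formula(50, 10, 10, 50))

    def test_extreme_table_statistic_equals_n(self):
        res = stats.chisq_2x2(0, 20, 20, 0)
        assert res.statistic == pytest.approx(40.0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    def test_formula_oracle_on_random_tables(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            with pytest.raises(stats.DegenerateInputError):
                stats.chisq_2x2(a, b, c, d)
            return
        res = stats.chisq_2x2(a, b, c, d)
        assert res.statistic == pytest.approx(chisq_2x2_formula(a, b, c, d))
        assert res.df == 1

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(stats.DegenerateInputError):
            stats.chisq_2x2(0, 0, 5, 7)


class TestBinomTwoSided:
    @pytest.mark.parametrize(
        "k,n,p0,expected",
        [
            (5, 10, 0.5, 1.0),  # modal outcome
            (2, 10, 0.5, 0.109375),  # 112/1024 by enumeration
            (0, 8, 0.5, 0.0078125),  # 2 * (1/2)^8
        ],
    )
    def test_enumerated_examples(self, k, n, p0, expected):
        assert stats.binom_two_sided(k, n, p0) == pytest.approx(expected)

    def test_exhaustive_small_n_against_enumeration(self):
        for n in range(1, 13):
            for k in range(n + 1):
                for p0 in (0.1, 0.268, 0.5, 0.7):
                    assert stats.binom_two_sided(k, n, p0) == pytest.approx(
                        binom_two_sided_enum(k, n, p0), rel=1e-9
                    ), (k, n, p0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stats.binom_two_sided(5, 4, 0.5)
        with pytest.raises(ValueError):
            stats.binom_two_sided(1, 4, 0.0)


class TestWelchT:
    def test_identical_groups_p_one(self):
        res = stats.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0)

    def test_antisymmetry(self):
        a = [0.1, 0.4, 0.9, 1.3]
        b = [2.0, 2.2, 1.7]
        r1 = stats.welch_t(a, b)
        r2 = stats.welch_t(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.statistic == pytest.approx(-r2.statistic)

    def test_separated_groups_agree_with_permutation_oracle(self):
        rng = np.random.default_rng(123)
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(2.0, 1.0, 50)
        res = stats.welch_t(a, b)
        assert res.p_value < 1e-6
        # permutation test can only resolve ~1/(n_perm+1); both must call
        # the separation overwhelming
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        n_extreme = 0
        n_perm = 999
        for _ in range(n_perm):
            rng.shuffle(pooled)
            n_extreme += abs(pooled[:50].mean() - pooled[50:].mean()) >= obs
        assert (n_extreme + 1) / (n_perm + 1) <= 0.005

    def test_degenerate_groups(self):
        with pytest.raises(stats.DegenerateInputError):
            stats.welch_t([1.0], [1.0, 2.0])
        with pytest.raises(stats.DegenerateInputError):
            stats.welch_t([1.0, 1.0, 1.0], [1.0, 2.0])


class TestBonferroni:
    def test_printed_methylation_threshold(self):
        assert stats.bonferroni_threshold(22374, 0.05) == pytest.approx(2.2e-6, rel=0.05)

    def test_single_test(self):
        assert stats.bonferroni_threshold(1, 0.05) == 0.05

    def test_expression_scale_threshold(self):
        assert stats.bonferroni_threshold(10925, 0.05) == pytest.approx(4.577e-6, rel=1e-3)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(1, 10**6), st.floats(1e-6, 0.999))
    def test_roundtrip_to_alpha(self, n, alpha):
        assert stats.bonferroni_threshold(n, alpha) * n == pytest.approx(alpha, rel=1e-12)
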