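"""Pearson-with-t, Hotelling dependent-correlation test, chi-square,
two-sample t — including a Monte-Carlo calibration of the Hotelling test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codontrend.assoc_stats import (
    chisq_2x2,
    hotelling_dependent_t,
    pearson_with_t,
    t_from_r,
    two_sample_t,
)


class TestPearsonWithT:
    def test_printed_worked_pair(self):
        # r = 0.61 at n = 59 corresponds to t = 5.81 (two decimal places).
        assert t_from_r(0.61, 59) == pytest.approx(5.81, abs=0.01)

    def test_perfect_correlation_sentinels(self):
        x = np.arange(10.0)
        res = pearson_with_t(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert math.isinf(res.t) and res.t > 0
        assert res.p == 0.0

    def test_zero_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to the trend
        res = pearson_with_t(x, y)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_pairwise_nan_exclusion(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        x_nan = x.copy()
        x_nan[:5] = np.nan
        res = pearson_with_t(x_nan, y)
        ref = pearson_with_t(x[5:], y[5:])
        assert res.n == 25
        assert res.r == pytest.approx(ref.r)

    @settings(deadline=None, max_examples=40)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=0.1, max_value=5.0),
        st.floats(min_value=-10.0, max_value=10.0),
    )
    def test_affine_invariance(self, seed, slope, intercept):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        base = pearson_with_t(x, y)
        up = pearson_with_t(slope * x + intercept, y)
        down = pearson_with_t(-slope * x + intercept, y)
        assert up.r == pytest.approx(base.r, abs=1e-9)
        assert down.r == pytest.approx(-base.r, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])  # n < 4
        with pytest.raises(ValueError):
            pearson_with_t([1.0] * 6, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])


class TestHotelling:
    def test_null_is_exactly_zero(self):
        res = hotelling_dependent_t(0.5, 0.5, 0.2, n=30)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.df == 27

    def test_frozen_oracle_value(self):
        # Independent hand evaluation of the 1940 formula for
        # (r12, r13, r23, n) = (0.61, 0.02, 0.40, 59).
        res = hotelling_dependent_t(0.61, 0.02, 0.40, n=59)
        assert res.t == pytest.approx(5.347090402267436, abs=1e-12)
        assert res.df == 56

    @settings(deadline=None, max_examples=60)
    @given(
        st.floats(min_value=-0.9, max_value=0.9),
        st.floats(min_value=-0.9, max_value=0.9),
        st.floats(min_value=-0.5, max_value=0.5),
        st.integers(min_value=5, max_value=200),
    )
    def test_antisymmetry(self, r12, r13, r23, n):
        try:
            fwd = hotelling_dependent_t(r12, r13, r23, n)
        except ValueError:
            return  # non-positive-definite triple
        rev = hotelling_dependent_t(r13, r12, r23, n)
        assert fwd.t == pytest.approx(-rev.t, abs=1e-12)

    def test_non_psd_triple_rejected(self):
        with pytest.raises(ValueError):
            hotelling_dependent_t(0.9, -0.9, 0.9, n=20)

    def test_williams_variant_close_to_1940_for_large_n(self):
        a = hotelling_dependent_t(0.6, 0.3, 0.4, n=200)
        b = hotelling_dependent_t(0.6, 0.3, 0.4, n=200, variant="williams")
        assert a.t == pytest.approx(b.t, rel=0.05)

    def test_type_one_error_calibration(self):
        # Under the null (two independent standard-normal features against a
        # shared third, n = 59), the empirical type-I error at alpha = 0.05
        # over 10,000 replicates must be 0.05 +/- 0.01.
        rng = np.random.default_rng(59)
        reps, n = 10_000, 59
        X = rng.standard_normal((reps, n, 3))
        Xc = X - X.mean(axis=1, keepdims=True)
        Xc /= np.linalg.norm(Xc, axis=1, keepdims=True)
        r12 = np.einsum("ij,ij->i", Xc[:, :, 0], Xc[:, :, 1])
        r13 = np.einsum("ij,ij->i", Xc[:, :, 0], Xc[:, :, 2])
        r23 = np.einsum("ij,ij->i", Xc[:, :, 1], Xc[:, :, 2])
        rejections = 0
        for a, b, c in zip(r12, r13, r23):
            if hotelling_dependent_t(float(a), float(b), float(c), n).p < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.01)


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        assert chisq_2x2(10, 90, 20, 180).chi2 == pytest.approx(0.0)

    def test_hand_formula_oracle(self):
        # Sum of (O - E)^2 / E for the table [[30, 70], [10, 90]] is 12.5.
        res = chisq_2x2(30, 70, 10, 90)
        assert res.chi2 == pytest.approx(12.5)
        assert res.df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_2x2(0, 0, 10, 90)

    def test_transpose_and_swap_invariance(self):
        base = chisq_2x2(30, 70, 10, 90).chi2
        assert chisq_2x2(30, 10, 70, 90).chi2 == pytest.approx(base)  # transpose
        assert chisq_2x2(90, 10, 70, 30).chi2 == pytest.approx(base)  # both swaps

    def test_continuity_correction_lowers_statistic(self):
        plain = chisq_2x2(12, 8, 5, 15).chi2
        corrected = chisq_2x2(12, 8, 5, 15, continuity=True).chi2
        assert corrected < plain


class TestTwoSampleT:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0]
        t, df, p = two_sample_t(a, a)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_shifted_copies_closed_form(self):
        # Equal-variance groups shifted by delta: t = delta / (s * sqrt(2/n)).
        a = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        delta = 2.5
        b = a + delta
        s = a.std(ddof=1)
        expected = delta / (s * math.sqrt(2 / a.size))
        t, df, p = two_sample_t(b, a)
        assert t == pytest.approx(expected)
        assert df == 8

    def test_group_difference_at_study_effect_sizes(self):
        # Group means 5 points apart with sd <= 4.4 at n = 37 vs 17 should
        # give a decisive t statistic.
        rng = np.random.default_rng(42)
        a = rng.normal(65.4, 4.4, size=37)
        b = rng.normal(70.4, 1.2, size=17)
        t, df, p = two_sample_t(a, b)
        assert abs(t) > 2.0
        assert p < 0.01

    def test_zero_pooled_variance(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])
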