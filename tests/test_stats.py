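"""Sex-comparison statistics, effect-size bands, correlations and the
blockwise variance partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biaperf.stats import (
    GroupSummary,
    blockwise_regression,
    classify_effect_size,
    cohens_d,
    pearson_correlation,
    shapiro_wilk,
    students_t_test,
)
from biaperf.types import InputError


class TestStudentsT:
    def test_identical_groups(self):
        t, df, p = students_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 4

    def test_hand_computed_example(self):
        t, df, p = students_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.021, abs=5e-4)

    def test_degenerate_zero_variance(self):
        t, _, p = students_t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        with pytest.raises(InputError):
            students_t_test([2.0, 2.0], [3.0, 3.0])

    def test_small_groups_rejected(self):
        with pytest.raises(InputError):
            students_t_test([1.0], [2.0, 3.0])

    def test_separated_cohorts_reject_strongly(self):
        # groups drawn at the two sexes' V̇O₂max distributions reject at
        # alpha = 0.001 in nearly all replicates
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            f = rng.normal(55.6, 4.1, 14)
            m = rng.normal(66.0, 3.2, 14)
            _, _, p = students_t_test(f, m)
            rejections += p < 0.001
        assert rejections / n_rep > 0.95

    def test_welch_option(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 5, 20)
        t_p, df_p, _ = students_t_test(a, b)
        t_w, df_w, _ = students_t_test(a, b, welch=True)
        assert df_w < df_p
        assert t_w != t_p


class TestEffectSizes:
    def test_threshold_uptake_effect_size(self):
        f = GroupSummary(n=14, mean=46.1, sd=4.6)
        m = GroupSummary(n=14, mean=54.9, sd=3.6)
        es = cohens_d(f, m)
        assert es.d == pytest.approx(2.13, abs=0.005)
        assert es.magnitude == "very large"

    def test_equal_means_trivial(self):
        g = GroupSummary(n=10, mean=5.0, sd=1.0)
        es = cohens_d(g, GroupSummary(n=10, mean=5.0, sd=2.0))
        assert es.d == 0.0
        assert es.magnitude == "trivial"

    def test_unit_summaries(self):
        es = cohens_d(
            GroupSummary(n=2, mean=0.5, sd=0.707), GroupSummary(n=2, mean=1.5, sd=0.707)
        )
        assert es.d == pytest.approx(1.414, abs=1e-3)
        assert es.magnitude == "large"

    def test_both_sds_zero_raises(self):
        with pytest.raises(InputError):
            cohens_d(GroupSummary(n=5, mean=1, sd=0), GroupSummary(n=5, mean=2, sd=0))

    @pytest.mark.parametrize(
        "d,label",
        [
            (0.14, "trivial"), (0.20, "small"), (0.30, "small"), (0.37, "small"),
            (0.60, "moderate"), (0.67, "moderate"), (0.88, "moderate"),
            (1.20, "large"), (1.97, "large"), (2.00, "large"),
            (2.13, "very large"), (2.15, "very large"), (2.86, "very large"),
            (3.36, "very large"), (0.0, "trivial"), (-0.88, "moderate"),
        ],
    )
    def test_band_map(self, d, label):
        assert classify_effect_size(d) == label

    @settings(derandomize=True, max_examples=50)
    @given(
        m1=st.floats(-10, 10), m2=st.floats(-10, 10),
        s1=st.floats(0.1, 5), s2=st.floats(0.1, 5), c=st.floats(0.1, 10),
    )
    def test_symmetry_and_scale_invariance(self, m1, m2, s1, s2, c):
        g1, g2 = GroupSummary(5, m1, s1), GroupSummary(5, m2, s2)
        d12 = cohens_d(g1, g2).d
        assert cohens_d(g2, g1).d == pytest.approx(d12)
        scaled = cohens_d(
            GroupSummary(5, c * m1, c * s1), GroupSummary(5, c * m2, c * s2)
        ).d
        assert scaled == pytest.approx(d12, rel=1e-9)


class TestPearson:
    def test_perfect_lines(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, [2 * v + 1 for v in x])[0] == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_computed(self):
        r, _ = pearson_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_zero_variance_raises(self):
        with pytest.raises(InputError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    @settings(derandomize=True, max_examples=30)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.1, 5.0),
        b=st.floats(-10.0, 10.0),
    )
    def test_affine_invariance_and_sign_flip(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r0, _ = pearson_correlation(x, y)
        r_aff, _ = pearson_correlation(a * x + b, y)
        r_neg, _ = pearson_correlation(-a * x + b, y)
        assert r_aff == pytest.approx(r0, abs=1e-9)
        assert r_neg == pytest.approx(-r0, abs=1e-9)


class TestShapiroWilk:
    def test_constant_raises(self):
        with pytest.raises(InputError):
            shapiro_wilk([3.0] * 10)

    def test_size_limits(self):
        with pytest.raises(InputError):
            shapiro_wilk([1.0, 2.0])

    def test_power_against_exponential(self):
        rng = np.random.default_rng(21)
        rejects = sum(
            shapiro_wilk(rng.exponential(size=50))[1] < 0.05 for _ in range(200)
        )
        assert rejects / 200 > 0.90

    def test_calibration_under_normality(self):
        rng = np.random.default_rng(22)
        rejects = sum(
            shapiro_wilk(rng.normal(size=50))[1] < 0.05 for _ in range(1000)
        )
        assert rejects / 1000 == pytest.approx(0.05, abs=0.02)


class TestBlockwiseRegression:
    def test_response_equals_first_predictor(self, rng):
        x1 = rng.normal(size=30)
        X = np.column_stack([x1, rng.normal(size=30), rng.normal(size=30)])
        part = blockwise_regression(x1, X)
        assert part.delta_r2[0] == pytest.approx(1.0, abs=1e-9)
        assert part.delta_r2[1] == pytest.approx(0.0, abs=1e-9)
        assert part.total_r2 == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_predictors_match_marginal_correlations(self, rng):
        # on a constructed orthogonal standardized design, each increment
        # equals the squared marginal correlation of that predictor with y
        n = 50
        raw = rng.normal(size=(n, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = q * np.sqrt(n - 1)  # centered, orthogonal, unit variance
        y = 0.7 * X[:, 0] - 0.4 * X[:, 1] + 0.2 * X[:, 2] + rng.normal(size=n)
        part = blockwise_regression(y, X)
        for k in range(3):
            r, _ = pearson_correlation(X[:, k], y)
            assert part.delta_r2[k] == pytest.approx(r**2, abs=1e-9)

    def test_partition_closure_any_order(self, rng):
        n = 40
        X = rng.normal(size=(n, 3))
        y = X @ np.array([1.0, -0.5, 0.25]) + rng.normal(size=n)
        base = blockwise_regression(y, X)
        for order in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            part = blockwise_regression(y, X[:, order])
            assert sum(part.delta_r2) == pytest.approx(part.total_r2, abs=1e-9)
            assert part.total_r2 == pytest.approx(base.total_r2, abs=1e-9)

    def test_collinear_predictor_named(self, rng):
        x1 = rng.normal(size=30)
        X = np.column_stack([x1, 2.0 * x1])
        with pytest.raises(InputError, match="x2"):
            blockwise_regression(rng.normal(size=30), X)

    def test_too_few_observations(self, rng):
        with pytest.raises(InputError):
            blockwise_regression(rng.normal(size=4), rng.normal(size=(4, 3)))

    def test_full_model_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 25
        X = rng.normal(size=(n, 3))
        y = X @ np.array([0.5, 0.3, -0.2]) + rng.normal(size=n)
        part = blockwise_regression(y, X)
        res = sm.OLS(y, sm.add_constant(X)).fit()
        assert part.total_r2 == pytest.approx(res.rsquared, abs=1e-9)
        assert part.p_value == pytest.approx(res.f_pvalue, abs=1e-12)
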