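"""Eligibility rules, normalizing transforms, covariate adjustment,
outlier fencing, and imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from agegaps.preprocess import (
    TransformSpec,
    adjust_for_ticv,
    apply_transform,
    fit_boxcox_lambda,
    fit_transform_spec,
    fit_zscore,
    flag_extreme_outliers,
    impute_cognitive_scores,
    invert_direction,
    iterative_impute,
    normality_statistic,
    residualize_age_sex,
    screen_eligibility,
    select_normalizing_transform,
)

DOMAINS = {
    "wordlist": "memory", "recall": "memory", "figures": "memory",
    "fluency": "language", "bnt": "language",
    "tmt_a": "speed", "tmt_b": "speed",
}
ALL_ZERO = {t: 0.0 for t in DOMAINS}


class TestScreenEligibility:
    def test_low_mmse_excludes(self):
        d = screen_eligibility(ALL_ZERO, mmse_raw=25, domain_map=DOMAINS)
        assert not d.include and "mmse_below_26" in d.reasons

    def test_clean_profile_included(self):
        d = screen_eligibility(ALL_ZERO, mmse_raw=30, domain_map=DOMAINS)
        assert d.include and d.reasons == []

    def test_single_severe_z_excludes(self):
        z = dict(ALL_ZERO, tmt_a=-1.6)
        d = screen_eligibility(z, 30, DOMAINS)
        assert not d.include and "z_below_minus_1_5:tmt_a" in d.reasons

    def test_two_subthreshold_in_one_domain_excludes(self):
        z = dict(ALL_ZERO, wordlist=-1.2, recall=-1.2)
        d = screen_eligibility(z, 30, DOMAINS)
        assert not d.include and "jak_bondi_two_in_domain:memory" in d.reasons

    def test_one_subthreshold_in_each_of_three_domains_excludes(self):
        z = dict(ALL_ZERO, wordlist=-1.2, fluency=-1.2, tmt_a=-1.2)
        d = screen_eligibility(z, 30, DOMAINS)
        assert not d.include and "jak_bondi_one_in_each_of_three" in d.reasons

    def test_missing_domain_assignment_errors(self):
        with pytest.raises(ValueError, match="domain"):
            screen_eligibility({"unknown_test": 0.0}, 30, DOMAINS)

    def test_include_iff_no_reasons(self):
        for z in (ALL_ZERO, dict(ALL_ZERO, tmt_b=-2.0)):
            d = screen_eligibility(z, 30, DOMAINS)
            assert d.include == (not d.reasons)

    @settings(max_examples=100, deadline=None)
    @given(
        zs=st.lists(st.floats(-3, 3), min_size=7, max_size=7),
        drop=st.integers(0, 6),
        delta=st.floats(0.1, 3),
    )
    def test_monotone_lowering_z_never_includes(self, zs, drop, delta):
        names = list(DOMAINS)
        base = dict(zip(names, zs))
        before = screen_eligibility(base, 30, DOMAINS)
        lowered = dict(base)
        lowered[names[drop]] -= delta
        after = screen_eligibility(lowered, 30, DOMAINS)
        if not before.include:
            assert not after.include


class TestBoxCox:
    def test_lognormal_sample_gives_lambda_near_zero(self, rng):
        lam, _ = fit_boxcox_lambda(np.exp(rng.standard_normal(10000)))
        assert abs(lam) < 0.1

    def test_normal_sample_gives_lambda_near_one(self, rng):
        lam, _ = fit_boxcox_lambda(100 + 5 * rng.standard_normal(10000))
        assert abs(lam - 1) < 0.3

    def test_squared_shifted_normal_gives_half(self, rng):
        lam, _ = fit_boxcox_lambda((rng.standard_normal(10000) + 6) ** 2)
        assert abs(lam - 0.5) < 0.15

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_fine_grid_profile_likelihood(self, seed):
        r = np.random.default_rng(seed)
        x = np.exp(0.3 * r.standard_normal(300)) * 5 + r.uniform(0, 1, 300)
        lam, shift = fit_boxcox_lambda(x)
        grid = np.linspace(-5, 5, 2001)
        lls = [stats.boxcox_llf(g, x + shift) for g in grid]
        assert abs(lam - grid[int(np.argmax(lls))]) <= 0.01

    def test_nonpositive_without_shift_errors(self):
        with pytest.raises(ValueError, match="nonpositive"):
            fit_boxcox_lambda(np.linspace(-1, 5, 50), shift=False)

    def test_automatic_shift_makes_values_positive(self):
        lam, shift = fit_boxcox_lambda(np.linspace(-2, 5, 50))
        assert shift == pytest.approx(3.0)


class TestApplyTransform:
    def test_zscore_of_small_sample(self):
        spec = fit_zscore("v", np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            apply_transform(spec, np.array([1.0, 2.0, 3.0])), [-1, 0, 1]
        )

    def test_boxcox_lambda_one_is_shift_by_one(self):
        spec = TransformSpec("v", "boxcox", lmbda=1.0, shift=0.0)
        x = np.array([1.0, 2.5, 7.0])
        np.testing.assert_allclose(apply_transform(spec, x), x - 1)

    def test_invert_twice_is_identity(self):
        x = np.array([2.5, 3.0, -1.0])
        np.testing.assert_array_equal(
            invert_direction("v", invert_direction("v", x)), x
        )

    def test_invert_negates(self):
        np.testing.assert_array_equal(
            invert_direction("v", np.array([2.5, 3.0])), [-2.5, -3.0]
        )

    def test_log_of_nonpositive_names_cell(self):
        spec = TransformSpec("wmh", "log_shift", shift=0.0)
        with pytest.raises(ValueError, match="wmh.*position 1"):
            apply_transform(spec, np.array([1.0, -2.0, 3.0]))

    def test_nan_passes_through(self):
        spec = fit_zscore("v", np.array([1.0, 2.0, 3.0]))
        out = apply_transform(spec, np.array([1.0, np.nan]))
        assert np.isnan(out[1]) and out[0] == -1

    def test_rank_inverse_normal_is_monotone_and_normalish(self, rng):
        x = np.exp(rng.standard_normal(500))
        out = apply_transform(TransformSpec("v", "rank_inverse_normal"), x)
        assert np.all(np.diff(out[np.argsort(x)]) >= 0)
        assert stats.shapiro(out).pvalue > 0.05


class TestSelectNormalizingTransform:
    def test_improves_normality_of_skewed_sample(self, rng):
        x = np.exp(rng.standard_normal(400))
        spec, out = select_normalizing_transform("v", x)
        assert spec.kind != "identity"
        assert normality_statistic(out) <= normality_statistic(x)

    def test_keeps_normal_sample_close_to_identity_quality(self, rng):
        x = rng.standard_normal(400)
        spec, out = select_normalizing_transform("v", x)
        assert stats.shapiro(out).pvalue > 0.01


class TestTicvAdjustment:
    def test_ratio_method(self):
        out = adjust_for_ticv(np.array([1500.0]), np.array([1.5e6]), method="ratio")
        assert out[0] == pytest.approx(1e-3)

    def test_residual_method_removes_ticv_correlation(self, rng):
        ticv = 1.5e6 + 1e5 * rng.standard_normal(300)
        vol = 0.002 * ticv + 50 * rng.standard_normal(300)
        adj = adjust_for_ticv(vol, ticv)
        assert abs(np.corrcoef(adj, ticv)[0, 1]) < 1e-10
        assert adj.mean() == pytest.approx(vol.mean())

    def test_constant_ticv_returns_input(self, rng):
        vol = rng.standard_normal(50) + 100
        ticv = np.full(50, 1.5e6)
        np.testing.assert_allclose(adjust_for_ticv(vol, ticv), vol)

    def test_nonpositive_ticv_errors(self):
        with pytest.raises(ValueError, match="positive"):
            adjust_for_ticv(np.array([1.0]), np.array([0.0]))


class TestImputeCognitive:
    def test_four_missing_excluded_three_imputed(self):
        Z = np.zeros((2, 19))
        Z[0, :4] = np.nan   # 4 missing -> excluded
        Z[1, :3] = np.nan   # 3 missing -> imputed
        filled, included = impute_cognitive_scores(Z, max_missing=3)
        assert not included[0] and included[1]
        assert not np.isnan(filled[1]).any()

    def test_imputed_value_is_subject_mean(self):
        Z = np.full((1, 19), 0.5)
        Z[0, 7] = np.nan
        filled, included = impute_cognitive_scores(Z)
        assert included[0] and filled[0, 7] == pytest.approx(0.5)

    def test_complete_matrix_unchanged(self, rng):
        Z = rng.standard_normal((5, 19))
        filled, included = impute_cognitive_scores(Z)
        np.testing.assert_array_equal(filled, Z)
        assert included.all()

    def test_all_missing_never_imputed(self):
        Z = np.full((1, 19), np.nan)
        _, included = impute_cognitive_scores(Z, max_missing=19)
        assert not included[0]


class TestOutlierFences:
    def test_flags_only_the_extreme_value(self):
        x = np.r_[np.arange(1.0, 21.0), 1000.0]
        assert flag_extreme_outliers(x).tolist() == [20]

    def test_constant_sample_flags_nothing(self):
        assert flag_extreme_outliers(np.full(10, 3.0)).size == 0

    def test_value_exactly_at_fence_not_flagged(self):
        # for [1..8, c], Q1=3, Q3=7, IQR=4 -> upper fence 19 exactly
        x = np.r_[np.arange(1.0, 9.0), 19.0]
        assert flag_extreme_outliers(x).size == 0
        x[-1] = 19.0 + 1e-9
        assert flag_extreme_outliers(x).tolist() == [8]

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=60))
    def test_matches_brute_force_rule(self, values):
        x = np.asarray(values)
        got = set(flag_extreme_outliers(x).tolist())
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        expect = {
            i for i, v in enumerate(x)
            if v < q1 - 3 * iqr or v > q3 + 3 * iqr
        }
        assert got == expect

    def test_requires_four_values(self):
        with pytest.raises(ValueError):
            flag_extreme_outliers(np.array([1.0, 2.0, 3.0]))


class TestResidualizeAgeSex:
    def test_strong_age_effect_removed(self, rng):
        age = rng.uniform(60, 95, 200)
        sex = (rng.random(200) < 0.5).astype(float)
        vals = 2 * age + 0.1 * rng.standard_normal(200)
        out, used, p = residualize_age_sex(vals, age, sex)
        assert used
        assert abs(np.corrcoef(out, age)[0, 1]) < 0.05
        assert out.mean() == pytest.approx(vals.mean(), abs=1e-8)

    def test_pure_noise_left_unchanged(self):
        r = np.random.default_rng(77)
        age = r.uniform(60, 95, 200)
        sex = (r.random(200) < 0.5).astype(float)
        vals = r.standard_normal(200)
        out, used, _ = residualize_age_sex(vals, age, sex)
        assert not used
        np.testing.assert_array_equal(out, vals)

    def test_idempotent_on_residualized_values(self, rng):
        age = rng.uniform(60, 95, 300)
        sex = (rng.random(300) < 0.5).astype(float)
        vals = 0.5 * age - 2 * sex + rng.standard_normal(300)
        once, used, _ = residualize_age_sex(vals, age, sex)
        assert used
        twice, _, _ = residualize_age_sex(once, age, sex)
        np.testing.assert_allclose(twice, once, atol=1e-8)

    def test_single_sex_falls_back_to_age_only(self, rng):
        age = rng.uniform(60, 95, 100)
        sex = np.ones(100)
        vals = 3 * age + rng.standard_normal(100)
        with pytest.warns(UserWarning, match="single-sex"):
            out, used, p = residualize_age_sex(vals, age, sex)
        assert used and "age_only" in p


class TestIterativeImpute:
    @staticmethod
    def _factor_table(n, seed, missing_rate=0.0):
        r = np.random.default_rng(seed)
        F = r.standard_normal((n, 3))
        L = r.uniform(0.5, 0.9, (8, 3))
        X = F @ L.T + 0.4 * r.standard_normal((n, 8))
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(8)])
        mask = r.random(df.shape) < missing_rate
        holey = df.mask(mask)
        return df, holey, mask

    def test_complete_table_unchanged(self):
        df, _, _ = self._factor_table(100, 0)
        pd.testing.assert_frame_equal(iterative_impute(df), df)

    def test_beats_column_mean_imputation(self):
        df, holey, mask = self._factor_table(400, 1, missing_rate=0.10)
        filled = iterative_impute(holey, seed=3)
        truth = df.to_numpy()[mask]
        ours = filled.to_numpy()[mask]
        means = holey.fillna(holey.mean()).to_numpy()[mask]
        rmse = lambda x: np.sqrt(np.mean((x - truth) ** 2))
        assert rmse(ours) < rmse(means)

    def test_deterministic_given_seed(self):
        _, holey, _ = self._factor_table(150, 2, missing_rate=0.1)
        pd.testing.assert_frame_equal(
            iterative_impute(holey, seed=5), iterative_impute(holey, seed=5)
        )

    def test_fully_missing_column_errors(self):
        _, holey, _ = self._factor_table(50, 3, missing_rate=0.05)
        holey["v0"] = np.nan
        with pytest.raises(ValueError, match="fully-missing"):
            iterative_impute(holey)

    def test_comparable_to_sklearn_iterative_imputer(self):
        """Sanity cross-check against an independent chained-equations
        implementation: both recover masked cells with similar accuracy."""
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer

        df, holey, mask = self._factor_table(300, 4, missing_rate=0.10)
        ours = iterative_impute(holey, seed=1).to_numpy()[mask]
        theirs = IterativeImputer(random_state=0).fit_transform(holey.to_numpy())[
            mask
        ]
        truth = df.to_numpy()[mask]
        rmse = lambda x: np.sqrt(np.mean((x - truth) ** 2))
        assert rmse(ours) <= 1.2 * rmse(theirs)


class TestTransformSpecContract:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown transform kind"):
            TransformSpec("v", "weird")

    def test_refit_reapplication_reproducible(self, rng):
        x = np.exp(rng.standard_normal(200))
        spec = fit_transform_spec("v", x, "boxcox")
        np.testing.assert_array_equal(
            apply_transform(spec, x), apply_transform(spec, x)
        )
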