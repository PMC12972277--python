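"""SIMPLS regression, stratified cross-validation, bias correction, and
age-gap properties."""

import collections

import numpy as np
import pytest
import statsmodels.api as sm

from agegaps.age_gap import (
    BiasCorrection,
    apply_bias_correction,
    compute_gap,
    crossval_age_prediction,
    estimate_age_gap,
    fit_bias_correction,
    fit_pls,
    pls_predict,
    prediction_metrics,
    stratified_age_folds,
    suggest_components,
)


def _toy(n=80, p=5, seed=0, noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = 72 + X @ beta + noise * rng.standard_normal(n)
    return X, y


class TestSimpls:
    def test_full_rank_pls_equals_ols(self):
        X, y = _toy(n=50, p=3, seed=1)
        model = fit_pls(X, y, n_components=3)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(
            pls_predict(model, X), ols.predict(sm.add_constant(X)), atol=1e-6
        )

    def test_exact_linear_relation_one_component(self):
        rng = np.random.default_rng(2)
        x1 = rng.standard_normal(60)
        x2 = rng.standard_normal(60)
        x1c = x1 - x1.mean()
        x2 = x2 - (x2 - x2.mean()) @ x1c / (x1c @ x1c) * x1c  # exactly orthogonal
        X = np.column_stack([x1, x2])
        y = 3 * x1 + 70
        model = fit_pls(X, y, n_components=1)
        r2 = prediction_metrics(pls_predict(model, X), y).r_squared
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_first_weight_proportional_to_covariance(self):
        X, y = _toy(seed=3)
        model = fit_pls(X, y, n_components=1)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        c = Z.T @ (y - y.mean())
        w = model.x_weights[:, 0]
        np.testing.assert_allclose(
            w / np.linalg.norm(w), c / np.linalg.norm(c), atol=1e-10
        )

    def test_scores_mutually_orthogonal(self):
        X, y = _toy(seed=4)
        model = fit_pls(X, y, n_components=4)
        Z = (X - model.x_center) / model.x_scale
        T = Z @ model.x_weights
        G = T.T @ T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_matches_nipals_for_univariate_response(self):
        """SIMPLS and NIPALS coincide for a single response; the sklearn
        NIPALS implementation serves as the independent cross-check."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = _toy(n=90, p=6, seed=5)
        for k in (1, 2, 4):
            ours = pls_predict(fit_pls(X, y, k), X)
            theirs = PLSRegression(n_components=k).fit(X, y).predict(X).ravel()
            np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_excess_components_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 4))
        X[:, 3] = X[:, 0] + X[:, 1]          # rank 3
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, rng.standard_normal(30), n_components=4)

    def test_explained_variance_full_rank_equals_ols_r2(self):
        X, y = _toy(n=70, p=4, seed=7, noise=2.0)
        model = fit_pls(X, y, n_components=4)
        ols_r2 = sm.OLS(y, sm.add_constant(X)).fit().rsquared
        assert np.cumsum(model.pct_var_y)[-1] == pytest.approx(100 * ols_r2, abs=1e-6)

    def test_explained_variance_bounded_for_noise(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((200, 5))
        y = rng.standard_normal(200)
        model = fit_pls(X, y, n_components=5)
        assert np.all(model.pct_var_y >= 0)
        assert np.cumsum(model.pct_var_y)[-1] <= 100 + 1e-9


class TestPlsPredict:
    def test_center_row_predicts_mean_age(self):
        X, y = _toy(seed=9)
        model = fit_pls(X, y, 2)
        assert pls_predict(model, model.x_center)[0] == pytest.approx(y.mean())

    def test_duplicated_row_duplicated_prediction(self):
        X, y = _toy(seed=10)
        model = fit_pls(X, y, 2)
        two = pls_predict(model, np.vstack([X[0], X[0]]))
        assert two[0] == two[1]

    def test_wrong_width_rejected(self):
        X, y = _toy(seed=11)
        model = fit_pls(X, y, 2)
        with pytest.raises(ValueError, match="columns"):
            pls_predict(model, X[:, :3])


class TestCrossValidation:
    def test_fold_sizes_for_346_subjects(self):
        age = np.random.default_rng(0).uniform(60, 95, 346)
        fa = stratified_age_folds(age, 10, seed=1)
        sizes = sorted(collections.Counter(fa.folds).values())
        assert sizes == [34] * 4 + [35] * 6

    def test_every_subject_in_exactly_one_fold(self):
        age = np.random.default_rng(1).uniform(60, 95, 120)
        fa = stratified_age_folds(age, 10, seed=2)
        assert fa.folds.size == 120
        assert set(fa.folds) == set(range(1, 11))

    def test_age_stratification_within_blocks(self):
        """Each consecutive age-sorted block of K subjects contains each
        fold exactly once."""
        age = np.random.default_rng(2).uniform(60, 95, 200)
        K = 10
        fa = stratified_age_folds(age, K, seed=3)
        order = np.argsort(age, kind="stable")
        for start in range(0, 200, K):
            block = fa.folds[order[start : start + K]]
            assert sorted(block) == list(range(1, K + 1))

    def test_pure_noise_gives_null_out_of_fold_r2(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((1000, 19))
        age = rng.uniform(60, 95, 1000)
        raw, _, _ = crossval_age_prediction(X, age, n_components=3, seed=5)
        assert np.corrcoef(raw, age)[0, 1] ** 2 < 0.05

    def test_deterministic_given_seed(self):
        X, y = _toy(n=120, seed=12)
        a1 = crossval_age_prediction(X, y, 2, seed=9)
        a2 = crossval_age_prediction(X, y, 2, seed=9)
        np.testing.assert_array_equal(a1[0], a2[0])
        np.testing.assert_array_equal(a1[1].folds, a2[1].folds)


class TestBiasCorrection:
    def test_perfect_predictions(self):
        age = np.linspace(60, 95, 50)
        bc = fit_bias_correction(age, age)
        assert bc.alpha == pytest.approx(1.0) and bc.beta == pytest.approx(0.0, abs=1e-10)

    def test_exact_line_recovered(self):
        age = np.linspace(60, 95, 50)
        bc = fit_bias_correction(0.5 * age + 35, age)
        assert bc.alpha == pytest.approx(0.5) and bc.beta == pytest.approx(35.0)

    def test_matches_normal_equation_oracle(self, rng):
        age = rng.uniform(60, 95, 200)
        pred = 0.6 * age + 25 + rng.standard_normal(200)
        bc = fit_bias_correction(pred, age)
        A = np.column_stack([age, np.ones(200)])
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ pred)
        assert bc.alpha == pytest.approx(slope, abs=1e-10)
        assert bc.beta == pytest.approx(intercept, abs=1e-10)

    def test_offset_correction_worked_example(self):
        bc = BiasCorrection(alpha=0.5, beta=35.0)
        out = apply_bias_correction(np.array([80.0]), np.array([70.0]), bc)
        assert out[0] == pytest.approx(80.0)   # 80 + (70 - (0.5*70 + 35))

    def test_identity_line_means_no_correction(self):
        raw = np.array([62.0, 75.0, 90.0])
        age = np.array([60.0, 74.0, 91.0])
        bc = BiasCorrection(alpha=1.0, beta=0.0)
        for variant in ("offset", "rescale"):
            bc.variant = variant
            np.testing.assert_allclose(apply_bias_correction(raw, age, bc), raw)

    def test_offset_nulls_age_dependence_of_gap(self, rng):
        age = rng.uniform(60, 95, 400)
        raw = 0.4 * age + 40 + 3 * rng.standard_normal(400)
        bc = fit_bias_correction(raw, age)
        corrected = apply_bias_correction(raw, age, bc)
        gap = compute_gap(corrected, age)
        assert abs(np.corrcoef(gap, age)[0, 1]) < 1e-8
        slope = np.polyfit(age, corrected, 1)[0]
        assert slope == pytest.approx(1.0, abs=1e-8)

    def test_rescale_with_flat_line_rejected(self):
        bc = BiasCorrection(alpha=0.0, beta=70.0, variant="rescale")
        with pytest.raises(ValueError, match="alpha"):
            apply_bias_correction(np.array([70.0]), np.array([70.0]), bc)

    def test_zero_age_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_bias_correction(np.array([70.0, 71.0]), np.array([70.0, 70.0]))


class TestGapAndMetrics:
    def test_gap_sign_convention(self):
        assert compute_gap(np.array([72.0]), np.array([70.0]))[0] == 2.0
        assert compute_gap(np.array([68.0]), np.array([70.0]))[0] < 0

    def test_perfect_and_inverted_predictions(self):
        age = np.linspace(60, 95, 40)
        m = prediction_metrics(age, age)
        assert m.pearson_r == pytest.approx(1.0) and m.mae == 0
        m = prediction_metrics(-age + 150, age)
        assert m.pearson_r == pytest.approx(-1.0) and m.r_squared == pytest.approx(1.0)

    def test_matches_direct_formulas(self, rng):
        pred = rng.standard_normal(100) + 75
        age = rng.standard_normal(100) + 75
        m = prediction_metrics(pred, age)
        r = ((pred - pred.mean()) @ (age - age.mean())) / (
            np.sqrt(((pred - pred.mean()) ** 2).sum() * ((age - age.mean()) ** 2).sum())
        )
        assert m.pearson_r == pytest.approx(r, abs=1e-12)
        assert m.mae == pytest.approx(np.abs(pred - age).mean(), abs=1e-12)
        assert m.mse == pytest.approx(((pred - age) ** 2).mean(), abs=1e-12)
        assert m.r_squared == pytest.approx(m.pearson_r**2, abs=1e-10)


class TestSuggestComponents:
    def test_elbow_curve(self):
        assert suggest_components([50, 70, 72, 72.5, 73], threshold=5) == 2

    def test_flat_curve(self):
        assert suggest_components([40, 40, 40], threshold=5) == 1

    def test_steady_gains_take_maximum(self):
        assert suggest_components([10, 20, 30, 40], threshold=5) == 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            suggest_components([])


class TestRecovery:
    def test_corrected_r2_close_to_generative_oracle(self, cohort350):
        """Cross-validated corrected-age R^2 tracks the R^2 of the refit
        generative linear model (bias-corrected in-sample OLS)."""
        from agegaps import preprocess as pp
        from agegaps.synthetic import COGNITIVE_VARS

        table, _ = cohort350
        age = table.age.to_numpy()
        Xcols = []
        for v in COGNITIVE_VARS:
            vals = table.data[v.name].to_numpy(float)
            if v.direction > 0:
                vals = -vals
            if v.skewed:
                vals = pp.apply_transform(pp.fit_transform_spec(v.name, vals, "boxcox"), vals)
            Xcols.append(pp.apply_transform(pp.fit_zscore(v.name, vals), vals))
        X = np.column_stack(Xcols)
        res, _ = estimate_age_gap(X, age, n_components=3, seed=1)
        cv_r2 = prediction_metrics(res.corrected_predicted_age, age).r_squared
        oracle_pred = sm.OLS(age, sm.add_constant(X)).fit().predict()
        bc = fit_bias_correction(oracle_pred, age)
        oracle_r2 = prediction_metrics(
            apply_bias_correction(oracle_pred, age, bc), age
        ).r_squared
        assert abs(cv_r2 - oracle_r2) <= 0.15
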