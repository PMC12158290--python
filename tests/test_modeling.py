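"""Splits, OLS/PLS fitting, and the R^2/RMSE metric definitions."""

import numpy as np
import pytest

from pearspec import (
    SplitSpec,
    coefficient_of_variation,
    evaluate_model,
    fit_pls,
    fit_two_band,
    loo_rmse,
    r_squared,
    rmse,
    select_n_components,
    split_samples,
)


class TestSplit:
    def test_sixty_twentyseven(self):
        spec = split_samples(87, SplitSpec(60, 27, seed=1))
        assert list(spec.assignment).count("train") == 60
        assert list(spec.assignment).count("valid") == 27

    def test_deterministic_per_seed(self):
        a = split_samples(87, SplitSpec(60, 27, seed=5))
        b = split_samples(87, SplitSpec(60, 27, seed=5))
        assert np.array_equal(a.assignment, b.assignment)
        c = split_samples(87, SplitSpec(60, 27, seed=6))
        assert not np.array_equal(a.assignment, c.assignment)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            split_samples(87, SplitSpec(60, 20, seed=1))

    def test_empty_validation_group_rejected(self):
        with pytest.raises(ValueError, match="validation"):
            SplitSpec(87, 0, seed=1)


class TestTwoBandOLS:
    def test_recovers_planted_affine_model(self):
        # a printed-style two-band equation used as planted truth
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 2))
        y = 0.057 - 0.851 * X[:, 0] + 0.073 * X[:, 1]
        model = fit_two_band(X, y, [516.0, 724.0], standardize=False)
        assert model.intercept == pytest.approx(0.057, abs=1e-8)
        np.testing.assert_allclose(model.coefficients, [-0.851, 0.073], atol=1e-8)
        icpt, coef = model.raw_affine()
        assert icpt == pytest.approx(0.057, abs=1e-8)
        np.testing.assert_allclose(coef, [-0.851, 0.073], atol=1e-8)

    def test_constant_response(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 2))
        model = fit_two_band(X, np.full(10, 46.0), [500.0, 700.0])
        np.testing.assert_allclose(model.coefficients, 0.0, atol=1e-10)
        np.testing.assert_allclose(model.predict(X), 46.0)

    def test_collinear_predictors_rejected_naming_bands(self):
        x1 = np.arange(10.0)
        with pytest.raises(ValueError, match=r"500.*700.*collinear"):
            fit_two_band(np.column_stack([x1, 2 * x1]), x1, [500.0, 700.0])

    def test_constant_predictor_rejected(self):
        X = np.column_stack([np.full(10, 0.3), np.arange(10.0)])
        with pytest.raises(ValueError, match="constant"):
            fit_two_band(X, np.arange(10.0), [455.0, 632.0])

    def test_standardized_and_raw_fits_predict_identically(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        y = 40 + 3 * X[:, 0] - X[:, 1] + rng.normal(0, 0.1, 30)
        std = fit_two_band(X, y, [450.0, 670.0], standardize=True)
        raw = fit_two_band(X, y, [450.0, 670.0], standardize=False)
        np.testing.assert_allclose(std.predict(X), raw.predict(X), atol=1e-8)


class TestPLS:
    def test_single_proportional_predictor_exact(self):
        x = np.arange(1.0, 11.0)[:, None]
        y = 3.5 * x[:, 0]
        model = fit_pls(x, y, 1)
        np.testing.assert_allclose(model.predict(x), y, atol=1e-10)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        model = fit_pls(X, y, 4)
        design = np.column_stack([np.ones(25), X])
        ols_pred = design @ np.linalg.lstsq(design, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), ols_pred, atol=1e-6)

    @pytest.mark.parametrize("n_components", [1, 2, 3, 5])
    def test_matches_sklearn_reference(self, n_components):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        ours = fit_pls(X, y, n_components, standardize=False)
        ref = PLSRegression(n_components=n_components, scale=False).fit(X, y)
        np.testing.assert_allclose(ours.predict(X), ref.predict(X).ravel(), atol=1e-6)

    def test_components_beyond_rank_rejected(self):
        x1 = np.arange(10.0)
        X = np.column_stack([x1, 2 * x1])  # rank 1 after centering
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, x1, 2)

    def test_loo_component_selection_prefers_signal_dimension(self):
        rng = np.random.default_rng(7)
        latent = rng.normal(size=40)
        X = np.column_stack([latent + rng.normal(0, 0.01, 40) for _ in range(3)])
        y = 5 * latent + rng.normal(0, 0.05, 40)
        k = select_n_components(X, y)
        assert 1 <= k <= 3
        assert loo_rmse(X, y, k) <= loo_rmse(X, y, 3) + 1e-9


class TestMetrics:
    def test_r_squared_examples(self):
        m = np.array([1.0, 2.0, 3.0])
        assert r_squared(m, m) == 1.0
        assert r_squared(m, np.full(3, m.mean())) == 0.0
        assert r_squared(m, np.array([1.0, 2.0, 4.0])) == pytest.approx(0.5)

    def test_rmse_examples(self):
        m = np.array([1.0, 2.0, 3.0])
        assert rmse(m, m) == 0.0
        assert rmse(m, m + 1) == pytest.approx(1.0)
        assert rmse(m, np.array([1.0, 2.0, 4.0])) == pytest.approx(np.sqrt(1 / 3))

    def test_matches_two_pass_reference(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(2, 40))
            m, p = rng.normal(size=n), rng.normal(size=n)
            if np.ptp(m) == 0:
                continue
            ref_r2 = 1 - np.sum((m - p) ** 2) / np.sum((m - np.mean(m)) ** 2)
            assert abs(r_squared(m, p) - ref_r2) < 1e-12
            assert abs(rmse(m, p) - np.sqrt(np.sum((m - p) ** 2) / n)) < 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rmse([], [])

    def test_coefficient_of_variation(self):
        assert coefficient_of_variation(50.0, 5.0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            coefficient_of_variation(0.0, 1.0)

    def test_evaluate_model_consistency(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 2))
        y = 45 + X[:, 0] - 2 * X[:, 1] + rng.normal(0, 0.2, 30)
        model = fit_two_band(X[:20], y[:20], [500.0, 700.0])
        ev = evaluate_model(model, X[:20], y[:20], X[20:], y[20:])
        assert ev.r2_train == pytest.approx(r_squared(y[:20], model.predict(X[:20])))
        assert ev.rmse_valid == pytest.approx(rmse(y[20:], model.predict(X[20:])))
        assert ev.n_train == 20 and ev.n_valid == 10
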