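"""NIPALS PLSR against least-squares oracles, component selection, metrics."""

import numpy as np
import pytest

import phenomap as pm
from phenomap.errors import DegenerateTargetError, GridMismatchError, RankError
from phenomap.plsr import beta_from_decomposition


def ols_fit(X, y):
    """Independent oracle: ordinary least squares with intercept."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef[0], coef[1:]


class TestFit:
    def test_orthonormal_design_recovers_sparse_coefficients(self):
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(40, 6)))
        X = Q  # orthonormal columns
        y = 2.0 * X[:, 0] - 1.0 * X[:, 1]
        model = pm.fit_plsr(X, y, n_lv=2)
        expected = np.zeros(6)
        expected[0], expected[1] = 2.0, -1.0
        # centered-X beta agrees with the OLS solution on centered data
        icpt, beta = ols_fit(X - X.mean(axis=0), y)
        np.testing.assert_allclose(model.coef_, beta, atol=1e-8)
        np.testing.assert_allclose(beta, expected, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_rank_predictions_equal_ols(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 10))
        y = rng.normal(size=50)
        model = pm.fit_plsr(X, y, n_lv=10)
        icpt, beta = ols_fit(X, y)
        np.testing.assert_allclose(model.predict(X), X @ beta + icpt, atol=1e-8)

    def test_constant_response_rejected(self):
        X = np.random.default_rng(3).normal(size=(10, 4))
        with pytest.raises(DegenerateTargetError):
            pm.fit_plsr(X, np.ones(10), n_lv=2)

    def test_components_beyond_rank_rejected(self):
        X = np.random.default_rng(4).normal(size=(6, 10))
        y = np.random.default_rng(5).normal(size=6)
        with pytest.raises(RankError):
            pm.fit_plsr(X, y, n_lv=8)  # a_max = n - 1 = 5

    def test_scores_orthogonal_and_rss_non_increasing(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 15))
        y = X[:, 0] - 0.5 * X[:, 3] + 0.1 * rng.normal(size=60)
        model = pm.fit_plsr(X, y, n_lv=8)
        T = model.x_scores_
        off = T.T @ T - np.diag(np.diag(T.T @ T))
        assert np.abs(off).max() < 1e-8
        rss = []
        for a in range(1, 9):
            beta = beta_from_decomposition(
                model.x_weights_, model.x_loadings_, model.y_loadings_, a
            )
            pred = (X - model.x_mean_) @ beta + model.y_mean_
            rss.append(np.sum((y - pred) ** 2))
        assert all(rss[i + 1] <= rss[i] + 1e-10 for i in range(len(rss) - 1))

    def test_decomposition_reconstructs_x(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        model = pm.fit_plsr(X, y, n_lv=5)
        recon = model.x_scores_ @ model.x_loadings_.T + model.x_residual_
        np.testing.assert_allclose(recon, X - model.x_mean_, atol=1e-10)

    def test_sklearn_estimator_contract(self):
        model = pm.PLSRegressionNIPALS(n_components=3)
        assert model.get_params() == {"n_components": 3}
        model.set_params(n_components=2)
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        assert model.fit(X, y) is model
        assert model.score(X, y) <= 1.0  # RegressorMixin R^2


class TestPredict:
    def test_mean_row_predicts_intercept(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(25, 7))
        y = rng.normal(size=25)
        model = pm.fit_plsr(X, y, n_lv=3)
        assert model.predict(model.x_mean_) == pytest.approx(model.intercept_, abs=1e-12)
        assert model.intercept_ == pytest.approx(y.mean())

    def test_doubling_spectrum_doubles_centered_prediction(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(25, 7))
        y = rng.normal(size=25)
        model = pm.fit_plsr(X, y, n_lv=3)
        x = X[0] + model.x_mean_
        p1 = model.predict(x) - model.intercept_ + float(model.x_mean_ @ model.coef_)
        p2 = model.predict(2 * x) - model.intercept_ + float(model.x_mean_ @ model.coef_)
        assert p2 == pytest.approx(2 * p1, abs=1e-8)

    def test_band_count_mismatch_rejected(self):
        rng = np.random.default_rng(11)
        model = pm.fit_plsr(rng.normal(size=(20, 6)), rng.normal(size=20), n_lv=2)
        with pytest.raises(GridMismatchError):
            model.predict(np.zeros((3, 9)))


class TestSelectComponents:
    def test_noiseless_rank_two_selects_two(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=(80, 2))
        loadings = rng.normal(size=(2, 20))
        X = scores @ loadings
        y = 1.5 * scores[:, 0] - 0.8 * scores[:, 1]
        assert pm.select_n_components(X, y, max_lv=8, seed=0) == 2

    def test_pure_noise_selects_one_under_one_se_rule(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(40, 12))
            y = rng.normal(size=40)
            if pm.select_n_components(X, y, max_lv=6, seed=seed) == 1:
                hits += 1
        assert hits >= 45  # >= 90% of runs

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(50, 10))
        y = X[:, 0] + 0.3 * rng.normal(size=50)
        a = pm.select_n_components(X, y, seed=4)
        assert a == pm.select_n_components(X, y, seed=4)

    def test_invalid_max_lv_rejected(self):
        with pytest.raises(ValueError):
            pm.select_n_components(np.zeros((10, 3)), np.arange(10.0), max_lv=0)


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = pm.evaluate(y, y, n_lv=1, partition="cal")
        assert m.r2_cal == 1.0 and m.sec == 0.0 and m.rmse == 0.0
        mv = pm.evaluate(y, y, n_lv=1, partition="val")
        assert mv.r2_val == 1.0 and mv.sep == 0.0

    def test_alternating_unit_errors_sep(self):
        y = np.zeros(4)
        y_hat = np.array([1.0, -1.0, 1.0, -1.0])
        with pytest.raises(DegenerateTargetError):
            pm.evaluate(y, y_hat, 1, "val")  # constant y has no TSS
        y = np.array([0.0, 1.0, 2.0, 3.0])
        m = pm.evaluate(y, y + y_hat, n_lv=1, partition="val")
        assert m.bias == pytest.approx(0.0)
        assert m.sep == pytest.approx(np.sqrt(4.0 / 3.0))

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        m = pm.evaluate(y, np.full(4, y.mean()), n_lv=1, partition="val")
        assert m.r2_val == pytest.approx(0.0)

    def test_sec_uses_model_degrees_of_freedom(self):
        rng = np.random.default_rng(14)
        y = rng.normal(size=30)
        y_hat = y + rng.normal(0, 0.1, size=30)
        rss = np.sum((y_hat - y) ** 2)
        m = pm.evaluate(y, y_hat, n_lv=4, partition="cal")
        assert m.sec == pytest.approx(np.sqrt(rss / (30 - 4 - 1)))

    def test_shift_invariance_except_bias(self):
        rng = np.random.default_rng(15)
        y = rng.normal(size=20)
        y_hat = y + rng.normal(0, 0.2, size=20)
        a = pm.evaluate(y, y_hat, 2, "val")
        b = pm.evaluate(y + 5.0, y_hat + 5.0, 2, "val")
        assert a.sep == pytest.approx(b.sep)
        assert a.bias == pytest.approx(b.bias)


def test_parameter_recovery_on_default_cohort(sg2_model):
    """Desk-scale analogue of the SWIR sg2 calibration: high validation R^2
    and sub-0.15 mg/g SEP on the synthetic cohort."""
    pre, model, mv = sg2_model
    assert mv.r2_val >= 0.9
    assert mv.sep <= 0.15
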