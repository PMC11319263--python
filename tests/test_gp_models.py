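"""Tests of the three whole-genome regression engines and their contract."""

import numpy as np
import pytest

from cgmgp.gp_models import (
    BayesCModel,
    BayesCSettings,
    CNNModel,
    CNNSettings,
    LassoModel,
    LassoSettings,
    TargetScaler,
    bayesc_fit,
    build_engine,
    cnn_fit,
    feature_lengths,
    lasso_fit,
    lasso_max_lambda,
)


def _marker_matrix(rng, n, p):
    return rng.integers(-1, 2, size=(n, p)).astype(float)


class TestTargetScaler:
    def test_roundtrip_identity(self, rng):
        Y = rng.normal(5.0, 2.0, size=(30, 3))
        scaler = TargetScaler.from_data(Y)
        assert np.allclose(scaler.inverse(scaler.transform(Y)), Y, atol=1e-12)

    def test_bounds_based_scaling(self):
        scaler = TargetScaler.from_bounds([(3.0, 8.0), (0.0, 0.1)])
        assert np.allclose(scaler.transform(np.array([[3.0, 0.1]])), [[0.0, 1.0]])


class TestLasso:
    def test_unpenalized_limit_equals_ols(self, rng):
        X = _marker_matrix(rng, 40, 8)
        y = X @ rng.normal(size=8) + rng.normal(size=40)
        model = lasso_fit(X, y, LassoSettings(lambda_=0.0))
        A = np.column_stack([np.ones(40), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.allclose(model.coefs_[:, 0], beta[1:], atol=1e-8)
        assert np.allclose(model.predict(X), A @ beta, atol=1e-8)

    def test_everything_shrunk_to_zero_at_lambda_max(self, rng):
        X = _marker_matrix(rng, 50, 20)
        y = X @ rng.normal(size=20) + rng.normal(size=50)
        Xs = (X - X.mean(0)) / X.std(0)
        lam_max = lasso_max_lambda(Xs, y)
        model = lasso_fit(X, y, LassoSettings(lambda_=lam_max * 1.0001))
        assert np.allclose(model.coefs_, 0.0)
        assert np.allclose(model.predict(X), y.mean(), atol=1e-8)

    def test_soft_threshold_closed_form_on_orthonormal_design(self, rng):
        # X'X = nI with mean-zero columns (so centering by the intercept is
        # a no-op): the lasso solution is soft-thresholded OLS per coordinate
        n, p = 64, 8
        A = rng.normal(size=(n, p))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        X = Q * np.sqrt(n)
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        lam = 0.3
        model = lasso_fit(X, y, LassoSettings(lambda_=lam, standardize=False))
        ols = X.T @ (y - y.mean()) / n
        expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
        assert np.allclose(model.coefs_[:, 0], expected, atol=1e-6)

    def test_kkt_conditions_on_cv_fit(self, rng):
        X = _marker_matrix(rng, 60, 120)
        y = X[:, :4] @ np.array([1.0, -1.0, 0.5, 0.8]) + rng.normal(size=60)
        model = lasso_fit(X, y)
        assert model.kkt_residual(X, y) <= 1e-6

    def test_constant_target_gives_intercept_only(self, rng):
        X = _marker_matrix(rng, 30, 10)
        with pytest.warns(UserWarning, match="constant target"):
            model = lasso_fit(X, np.full(30, 3.5))
        assert np.allclose(model.predict(X), 3.5)


class TestBayesC:
    def test_pi_one_returns_train_mean_exactly(self, rng):
        X = _marker_matrix(rng, 25, 15)
        y = rng.normal(size=25)
        model = bayesc_fit(X, y, BayesCSettings(pi=1.0, iterations=400, burn_in=100, seed=0))
        assert np.allclose(model.predict(X), y.mean(), atol=1e-12)
        assert np.allclose(model.effects_, 0.0)

    def test_pi_zero_fixed_variances_match_ridge(self, rng):
        # with every SNP included and variances held fixed, the posterior
        # mean of the effects is the ridge solution
        n, p = 20, 10
        X = rng.normal(size=(n, p))
        X -= X.mean(axis=0)
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        sa2, se2 = 0.5, 1.0
        model = bayesc_fit(X, y, BayesCSettings(
            pi=0.0, iterations=42000, burn_in=2000, thin=2,
            fixed_sigma_a2=sa2, fixed_sigma_e2=se2, seed=7,
        ))
        ridge = np.linalg.solve(X.T @ X + (se2 / sa2) * np.eye(p), X.T @ (y - y.mean()))
        # Monte-Carlo standard error per effect from the known posterior sd
        post_sd = np.sqrt(se2 * np.diag(np.linalg.inv(X.T @ X + (se2 / sa2) * np.eye(p))))
        mcse = 3.0 * post_sd / np.sqrt(model.posterior_[0]["n_samples"] / 20.0)  # autocorr guard
        assert np.all(np.abs(model.effects_[:, 0] - ridge) < np.maximum(mcse, 0.02))

    def test_chain_reproducible_given_seed(self, rng):
        X = _marker_matrix(rng, 30, 40)
        y = rng.normal(size=30)
        cfg = BayesCSettings(iterations=600, burn_in=200, thin=2, seed=11)
        a = bayesc_fit(X, y, cfg)
        b = bayesc_fit(X, y, cfg)
        assert np.array_equal(a.effects_, b.effects_)
        assert a.intercepts_[0] == b.intercepts_[0]

    def test_residual_variance_covers_truth_on_pure_noise(self, rng):
        X = _marker_matrix(rng, 100, 60)
        y = rng.normal(0.0, 2.0, size=100)
        model = bayesc_fit(X, y, BayesCSettings(iterations=4000, burn_in=1000, thin=3, seed=3))
        post = model.posterior_[0]
        assert abs(post["sigma_e2"] - y.var()) <= 2.0 * max(post["sigma_e2_sd"], 0.3)

    def test_effect_recovery_on_sparse_simulated_trait(self):
        """10 true QTL among 500 markers, n=300, h2=0.8: posterior-mean
        effects correlate with the truth (median over 5 seeds)."""
        correlations = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = _marker_matrix(rng, 300, 500)
            beta = np.zeros(500)
            beta[rng.choice(500, size=10, replace=False)] = rng.normal(0.0, 1.0, 10)
            g = X @ beta
            e = rng.normal(0.0, g.std() * 0.5, size=300)  # h2 = 0.8
            model = bayesc_fit(X, g + e, BayesCSettings(
                iterations=3000, burn_in=1000, thin=2, seed=seed,
            ))
            correlations.append(np.corrcoef(model.effects_[:, 0], beta)[0, 1])
        assert np.median(correlations) > 0.6

    def test_invalid_pi_rejected(self):
        with pytest.raises(ValueError, match="pi"):
            BayesCModel(BayesCSettings(pi=1.5))

    def test_prediction_is_row_wise(self, rng):
        X = _marker_matrix(rng, 30, 20)
        y = X[:, 0] + rng.normal(size=30)
        model = bayesc_fit(X, y, BayesCSettings(iterations=500, burn_in=100, seed=1))
        X1, X2 = _marker_matrix(rng, 5, 20), _marker_matrix(rng, 7, 20)
        stacked = model.predict(np.vstack([X1, X2]))
        assert np.allclose(stacked, np.concatenate([model.predict(X1), model.predict(X2)]))


class TestCNN:
    def test_feature_length_chain(self):
        assert feature_lengths(2000, (1, 3, 5, 5, 5)) == [2000, 667, 134, 27, 6]

    def test_constant_target_learned(self, rng):
        X = _marker_matrix(rng, 40, 400)
        Y = np.full(40, 7.0)
        model = cnn_fit(X, Y, CNNSettings(channels=(4, 8, 8, 8, 8), epochs=30,
                                          batch_size=8, seed=0))
        assert model.history_["train"][-1] < 1e-2
        assert np.allclose(model.predict(X), 7.0, atol=0.5)

    def test_multi_output_head_for_parameter_mode(self, rng):
        X = _marker_matrix(rng, 30, 400)
        Y = rng.normal(size=(30, 8))
        model = cnn_fit(X, Y, CNNSettings(channels=(4, 4, 4, 4, 4), epochs=2,
                                          batch_size=8, seed=0))
        assert model.params_[-1].shape == (8,)  # output bias: one per parameter
        assert model.predict(X).shape == (30, 8)

    def test_predictions_bounded_by_scaler_range(self, rng):
        X = _marker_matrix(rng, 30, 400)
        y = rng.normal(10.0, 3.0, size=30)
        model = cnn_fit(X, y, CNNSettings(channels=(4, 4, 4, 4, 4), epochs=3,
                                          batch_size=8, seed=1))
        pred = model.predict(_marker_matrix(rng, 50, 400))
        assert pred.min() >= model.scaler.mins[0] - 1e-9
        assert pred.max() <= model.scaler.maxs[0] + 1e-9

    def test_deterministic_given_seed(self, rng):
        X = _marker_matrix(rng, 25, 400)
        y = rng.normal(size=25)
        cfg = CNNSettings(channels=(4, 4, 4, 4, 4), epochs=3, batch_size=8, seed=5)
        a = cnn_fit(X, y, cfg).predict(X)
        b = cnn_fit(X, y, cfg).predict(X)
        assert np.array_equal(a, b)

    def test_pure_interaction_trait_is_invisible_to_lasso(self):
        """A product of two markers carries no additive signal: the lasso
        shrinks everything to zero and falls back to the train mean (the
        convolutional engine's ability to pick such signals up is asserted
        at study scale in the acceptance suite)."""
        rng = np.random.default_rng(8)
        X = _marker_matrix(rng, 300, 400)
        y = (X[:, 100] * X[:, 101]) * 2.0 + rng.normal(0.0, 0.3, 300)
        train, test = np.arange(240), np.arange(240, 300)
        lasso = lasso_fit(X[train], y[train])
        pred = lasso.predict(X[test])
        assert pred.std() < 1e-8 or abs(np.corrcoef(pred, y[test])[0, 1]) < 0.3


def test_linear_engines_agree_on_additive_truth():
    """On a purely additive trait (h2 = 0.8) the lasso and Bayes C reach
    predictive abilities within 0.1 of one another (median of 5 seeds)."""
    from cgmgp.gp_models import BayesCSettings, bayesc_fit

    pa = {"lasso": [], "bayesc": []}
    for seed in range(5):
        rng = np.random.default_rng(300 + seed)
        X = _marker_matrix(rng, 300, 1000)
        beta = np.zeros(1000)
        beta[rng.choice(1000, size=50, replace=False)] = rng.normal(size=50)
        g = X @ beta
        y = g + rng.normal(0.0, g.std() * 0.5, 300)  # h2 = 0.8
        train, test = np.arange(240), np.arange(240, 300)
        m_l = lasso_fit(X[train], y[train])
        m_b = bayesc_fit(X[train], y[train],
                         BayesCSettings(iterations=2000, burn_in=500, thin=3, seed=seed))
        pa["lasso"].append(np.corrcoef(m_l.predict(X[test]), y[test])[0, 1])
        pa["bayesc"].append(np.corrcoef(m_b.predict(X[test]), y[test])[0, 1])
    assert abs(np.median(pa["lasso"]) - np.median(pa["bayesc"])) <= 0.1


class TestEngineContract:
    def test_identical_interface_across_engines(self, rng):
        X = _marker_matrix(rng, 40, 400)
        y = X[:, 3] + rng.normal(0.0, 0.5, 40)
        settings = {
            "lasso": {},
            "bayesc": {"iterations": 400, "burn_in": 100},
            "cnn": {"channels": (4, 4, 4, 4, 4), "epochs": 2, "batch_size": 8},
        }
        for name, cfg in settings.items():
            model = build_engine(name, **cfg).fit(X, y)
            pred = model.predict(X)
            assert pred.shape == y.shape, name
            assert np.all(np.isfinite(pred)), name

    def test_marker_count_mismatch_rejected(self, rng):
        X = _marker_matrix(rng, 30, 50)
        model = lasso_fit(X, rng.normal(size=30))
        with pytest.raises(ValueError, match="mismatch"):
            model.predict(_marker_matrix(rng, 5, 49))

    def test_unknown_engine_rejected(self):
        with pytest.raises(ValueError, match="unknown engine"):
            build_engine("gblup")


class TestCNNGradients:
    @pytest.mark.parametrize("activation", ["relu", "relu_softmax"])
    def test_backward_matches_numeric_gradient(self, activation):
        """Hand-derived backward passes agree with central differences."""
        from cgmgp.gp_models.cnn import CNNModel

        rng = np.random.default_rng(0)
        X = rng.integers(-1, 2, size=(4, 50)).astype(float)
        Y = rng.uniform(0.2, 0.8, size=(4, 3))
        model = CNNModel(
            CNNSettings(kernels=(5, 3, 3), strides=(1, 2, 3), channels=(3, 4, 4),
                        dense_units=6, hidden_activation=activation, seed=1),
            scaler=TargetScaler(np.zeros(3), np.ones(3)),
        )
        params = model._init_params(50, 3, np.random.default_rng(1))

        def loss(params):
            pred, cache = model._forward(X, params)
            value, dout = model._loss_grad(pred, Y)
            return value, dout, cache

        _, dout, cache = loss(params)
        grads = model._backward(X, dout, params, cache)
        eps, worst = 1e-6, 0.0
        for i, p in enumerate(params):
            for _ in range(min(p.size, 4)):
                idx = tuple(rng.integers(0, d) for d in p.shape) if p.ndim else ()
                orig = p[idx]
                p[idx] = orig + eps
                up, *_ = loss(params)
                p[idx] = orig - eps
                down, *_ = loss(params)
                p[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[i][idx]
                worst = max(worst, abs(numeric - analytic)
                            / max(abs(numeric), abs(analytic), 1e-8))
        assert worst < 1e-5
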