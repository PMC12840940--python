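"""Splitting, z-scoring, fusion weighting, PLSR and evaluation contracts."""

import numpy as np
import pytest

from plumfusion.regression import (
    ColumnStandardizer,
    CVPLSRegression,
    FusedPLSRegressor,
    FusionSpec,
    evaluate,
    fuse,
    learn_fusion_weights,
    plsr_fit,
    plsr_predict,
    select_n_latent,
    train_test_split_ids,
    zscore_apply,
    zscore_fit,
)


def nipals_pls(X, y, n_components):
    """Textbook single-response NIPALS PLS1: independent reference oracle.

    Returns the regression coefficient vector on centered data plus the
    centering parameters, so predictions are x @ b + (ybar - xbar @ b).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    xbar, ybar = X.mean(axis=0), y.mean()
    E, f = X - xbar, y - ybar
    W, P, Q = [], [], []
    for _ in range(n_components):
        w = E.T @ f
        w = w / np.linalg.norm(w)
        t = E @ w
        tt = t @ t
        p = E.T @ t / tt
        q = (f @ t) / tt
        E = E - np.outer(t, p)
        f = f - q * t
        W.append(w), P.append(p), Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    b = W @ np.linalg.solve(P.T @ W, Q)
    return b, xbar, ybar


class TestSplit:
    def test_seventy_thirty_arithmetic(self):
        tr, te = train_test_split_ids([f"s{i}" for i in range(120)], 0.7, 1)
        assert len(tr) == 84 and len(te) == 36

    def test_partition_properties(self):
        ids = [f"s{i}" for i in range(37)]
        tr, te = train_test_split_ids(ids, 0.7, 5)
        assert set(tr) | set(te) == set(ids)
        assert set(tr) & set(te) == set()

    def test_seed_determinism(self):
        ids = [f"s{i}" for i in range(50)]
        assert train_test_split_ids(ids, 0.7, 9) == train_test_split_ids(ids, 0.7, 9)

    @pytest.mark.parametrize("ids,ratio", [(["a"], 0.5), (["a", "b"], 0.99), (["a", "b"], 1.5)])
    def test_degenerate_splits_rejected(self, ids, ratio):
        with pytest.raises(ValueError):
            train_test_split_ids(ids, ratio, 0)


class TestZScore:
    def test_sample_sd_contract(self):
        std = zscore_fit(np.array([[2.0], [4.0], [6.0]]))
        assert np.allclose(zscore_apply(std, np.array([[2.0], [4.0], [6.0]])).ravel(),
                           [-1.0, 0.0, 1.0])

    def test_train_columns_standardized(self, rng):
        X = rng.normal(5, 3, size=(40, 6))
        Z = zscore_fit(X).transform(X)
        assert np.all(np.abs(Z.mean(axis=0)) < 1e-12)
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0)

    def test_width_mismatch_rejected(self, rng):
        std = zscore_fit(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError):
            std.transform(rng.normal(size=(3, 5)))

    def test_zero_variance_column_named(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ValueError, match="column 1"):
            zscore_fit(X)


class TestFusionWeights:
    def test_exact_linear_interpolation_regime(self, rng):
        """Noiseless y linear in 3 standardized features: per-feature OLS
        recovers |true coefficients| and interpolates."""
        n = 50
        Zs = zscore_fit(rng.normal(size=(n, 2))).transform(rng.normal(size=(n, 2)))
        Zs = (Zs - Zs.mean(0)) / Zs.std(0, ddof=1)
        Zv = rng.normal(size=(n, 1))
        Zv = (Zv - Zv.mean(0)) / Zv.std(0, ddof=1)
        y = 2.0 * Zs[:, 0] - 1.5 * Zs[:, 1] + 0.5 * Zv[:, 0] + 4.0
        spec = learn_fusion_weights(Zs, Zv, y, mode="per_feature")
        assert np.allclose(spec.spectral_weights, [2.0, 1.5], atol=1e-8)
        assert np.allclose(spec.visual_weights, [0.5], atol=1e-8)

    def test_per_feature_matches_normal_equations(self, rng):
        n = 60
        Zs, Zv = rng.normal(size=(n, 5)), rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        spec = learn_fusion_weights(Zs, Zv, y, mode="per_feature")
        A = np.column_stack([np.ones(n), Zs, Zv])
        beta = np.linalg.solve(A.T @ A, A.T @ y)[1:]
        assert np.allclose(np.concatenate([spec.spectral_weights, spec.visual_weights]),
                           np.abs(beta), atol=1e-8)

    def test_per_block_downweights_noise_block(self):
        """Visual block of pure noise gets a small scalar relative to a
        strongly predictive spectral block (median over 20 seeds)."""
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 80
            latent = rng.normal(size=n)
            Zs = np.column_stack([latent + rng.normal(0, 0.05, n) for _ in range(6)])
            Zv = rng.normal(size=(n, 4))
            y = latent + rng.normal(0, 0.05, n)
            spec = learn_fusion_weights(Zs, Zv, y, mode="per_block")
            ratios.append(abs(spec.visual_weights[0]) / abs(spec.spectral_weights[0]))
        assert np.median(ratios) < 0.2

    def test_rank_deficiency_warns_not_fails(self, rng):
        Zs = rng.normal(size=(10, 8))
        Zv = rng.normal(size=(10, 8))
        y = rng.normal(size=10)
        with pytest.warns(UserWarning, match="rank-deficient"):
            learn_fusion_weights(Zs, Zv, y, mode="per_feature")


class TestFuse:
    def test_zeroed_visual_block_equals_spectral_only_model(self, rng):
        n = 40
        Zs, Zv = rng.normal(size=(n, 6)), rng.normal(size=(n, 3))
        y = Zs @ rng.normal(size=6) + rng.normal(0, 0.1, n)
        spec = FusionSpec(np.ones(6), np.zeros(3))
        fused = fuse(Zs, Zv, spec)
        assert np.all(fused[:, 6:] == 0)
        m_fused = plsr_fit(fused, y, 4)
        m_spec = plsr_fit(Zs, y, 4)
        assert np.allclose(plsr_predict(m_fused, fused), plsr_predict(m_spec, Zs), atol=1e-8)

    def test_unit_weights_are_concatenation(self, rng):
        Zs, Zv = rng.normal(size=(5, 4)), rng.normal(size=(5, 2))
        fused = fuse(Zs, Zv, FusionSpec(np.ones(4), np.ones(2)))
        assert np.array_equal(fused, np.hstack([Zs, Zv]))

    def test_spectral_block_comes_first(self, rng):
        Zs, Zv = rng.normal(size=(5, 4)), rng.normal(size=(5, 2))
        fused = fuse(Zs, Zv, FusionSpec(np.full(4, 2.0), np.full(2, 3.0)))
        assert np.allclose(fused[:, :4], 2.0 * Zs)
        assert np.allclose(fused[:, 4:], 3.0 * Zv)

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse(rng.normal(size=(5, 3)), rng.normal(size=(5, 2)),
                 FusionSpec(np.ones(4), np.ones(2)))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            FusionSpec(np.zeros(3), np.zeros(2))


class TestPLSR:
    def test_univariate_equals_simple_regression(self, rng):
        x = rng.normal(size=(30, 1))
        y = 2.5 * x[:, 0] + 1.0 + rng.normal(0, 0.3, 30)
        model = plsr_fit(x, y, 1)
        slope, intercept = np.polyfit(x[:, 0], y, 1)
        assert np.allclose(plsr_predict(model, x), slope * x[:, 0] + intercept, atol=1e-10)

    def test_full_rank_equals_multiple_ols(self, rng):
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, 0.2, 40)
        model = plsr_fit(X, y, 5)
        A = np.column_stack([np.ones(40), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.allclose(plsr_predict(model, X), A @ beta, atol=1e-8)

    def test_matches_nipals_oracle(self, rng):
        """3-component fit on a 10x6 matrix with 3-dimensional latent
        structure reproduces the textbook NIPALS coefficients exactly."""
        T = rng.normal(size=(10, 3))
        L = rng.normal(size=(3, 6))
        X = T @ L
        y = T @ np.array([1.0, -0.5, 2.0])
        model = plsr_fit(X, y, 3)
        b, xbar, ybar = nipals_pls(X, y, 3)
        assert np.allclose(model.coef_.ravel(), b, atol=1e-8)
        preds = X @ b + (ybar - xbar @ b)
        assert np.allclose(plsr_predict(model, X), preds, atol=1e-8)
        assert evaluate(y, plsr_predict(model, X))["r2"] == pytest.approx(1.0, abs=1e-8)

    def test_affine_equivariance_in_y(self, rng):
        X = rng.normal(size=(25, 4))
        y = X @ np.array([1.0, 2.0, -1.0, 0.5]) + rng.normal(0, 0.1, 25)
        p1 = plsr_predict(plsr_fit(X, y, 2), X)
        p2 = plsr_predict(plsr_fit(X, y + 7.0, 2), X)
        assert np.allclose(p2, p1 + 7.0, atol=1e-8)

    def test_parameter_validation(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            plsr_fit(X, y, 0)
        with pytest.raises(ValueError):
            plsr_fit(X, y, 5)
        with pytest.raises(ValueError):
            plsr_fit(X, np.full(10, 3.0), 2)


class TestSelectNLatent:
    def test_recovers_intrinsic_dimension_one(self, rng):
        scores = rng.normal(size=60)
        loadings = rng.normal(size=8)
        X = np.outer(scores, loadings) + rng.normal(0, 0.01, size=(60, 8))
        y = scores  # the single latent direction, noiseless
        k, trace = select_n_latent(X, y, max_latent=6, seed=42)
        assert k == 1
        assert trace[0] < 0.05

    def test_single_candidate(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        k, trace = select_n_latent(X, y, max_latent=1)
        assert k == 1 and trace.size == 1

    def test_trace_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        _, t1 = select_n_latent(X, y, 5, seed=42)
        _, t2 = select_n_latent(X, y, 5, seed=42)
        assert np.array_equal(t1, t2)

    def test_infeasible_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            select_n_latent(rng.normal(size=(3, 4)), rng.normal(size=3), 2, k_folds=5)


class TestEvaluate:
    def test_perfect_prediction(self):
        m = evaluate([1, 2, 3], [1, 2, 3])
        assert m["r2"] == 1.0 and m["rmse"] == 0.0 and np.isinf(m["rpd"])

    def test_mean_predictor_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate(y, np.full(4, y.mean()))
        assert m["r2"] == pytest.approx(0.0)

    def test_rpd_definition_ratio(self, rng):
        y = rng.normal(size=500)
        y = (y - y.mean()) / y.std(ddof=1)  # sd exactly 1
        pred = y + 0.5 * np.sign(np.arange(500) % 2 - 0.5)  # rmse exactly 0.5
        m = evaluate(y, pred)
        assert m["rpd"] == pytest.approx(np.std(y, ddof=1) / m["rmse"])
        assert m["rpd"] == pytest.approx(2.0, rel=1e-12)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestNoLeakage:
    def test_fitted_model_independent_of_test_data(self, rng):
        """Replacing the test partition entirely leaves every fitted
        parameter identical — nothing stateful ever sees test rows."""
        n, ps, pv = 60, 12, 4
        Xs = rng.normal(size=(n, ps))
        Xv = rng.normal(size=(n, pv))
        y = Xs @ rng.normal(size=ps) + rng.normal(0, 0.5, n)
        X = np.hstack([Xs, Xv])
        model_a = FusedPLSRegressor(n_spectral=ps).fit(X, y)
        model_b = FusedPLSRegressor(n_spectral=ps).fit(X, y)
        X_new = rng.normal(size=(10, ps + pv))  # arbitrary unseen data
        assert np.array_equal(model_a.predict(X_new), model_b.predict(X_new))
        assert np.array_equal(model_a.fusion_spec_.spectral_weights,
                              model_b.fusion_spec_.spectral_weights)
        assert model_a.n_components_ == model_b.n_components_

    def test_pipeline_stages_fit_on_train_only(self, rng):
        """Permuting or corrupting test-partition rows does not change the
        standardizer, fusion weights or PLS coefficients learned on train."""
        n, ps, pv = 50, 10, 3
        Xs = rng.normal(size=(n, ps))
        Xv = rng.normal(size=(n, pv))
        y = Xs @ rng.normal(size=ps) + rng.normal(0, 0.3, n)
        X = np.hstack([Xs, Xv])
        tr = np.arange(35)
        model = FusedPLSRegressor(n_spectral=ps)
        fitted_1 = model.fit(X[tr], y[tr])
        w1 = fitted_1.fusion_spec_.spectral_weights.copy()
        coef1 = fitted_1.pls_.coef_.copy()
        # "new" dataset: same train rows, wildly different test rows
        fitted_2 = FusedPLSRegressor(n_spectral=ps).fit(X[tr], y[tr])
        assert np.array_equal(w1, fitted_2.fusion_spec_.spectral_weights)
        assert np.array_equal(coef1, fitted_2.pls_.coef_)


class TestFusedRegressor:
    def test_sklearn_protocol(self, rng):
        from sklearn.base import clone

        est = FusedPLSRegressor(n_spectral=5, max_latent=4)
        params = est.get_params()
        assert params["n_spectral"] == 5
        cloned = clone(est)
        X = rng.normal(size=(40, 8))
        y = X[:, 0] + rng.normal(0, 0.1, 40)
        cloned.fit(X, y)
        assert hasattr(cloned, "fusion_spec_") and cloned.predict(X).shape == (40,)

    def test_missing_visual_block_rejected(self, rng):
        est = FusedPLSRegressor(n_spectral=8)
        with pytest.raises(ValueError):
            est.fit(rng.normal(size=(20, 8)), rng.normal(size=20))
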