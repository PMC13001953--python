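"""Metrics arithmetic, bootstrap error distributions, dominance, diagnostics."""

import math

import numpy as np
import pytest

from growthstack.evaluation import (check_convergence, compute_metrics,
                                    dirichlet_weights, dominance_matrix,
                                    error_samples, joint_error_samples,
                                    percent_rmse_reduction)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        row = compute_metrics(y, y, n_params=1)
        assert row.rmse == 0.0
        assert row.mae == 0.0
        assert row.r2 == pytest.approx(1.0)

    def test_hand_arithmetic_two_points(self):
        # RSS = 2, TSS = 2 -> RMSE 1, MAE 1, R^2 = 0
        row = compute_metrics([0.0, 2.0], [1.0, 1.0], n_params=1, strict=False)
        assert row.rmse == pytest.approx(1.0)
        assert row.mae == pytest.approx(1.0)
        assert row.r2 == pytest.approx(0.0)

    def test_constant_mean_predictor_scores_zero_r2(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=100)
        row = compute_metrics(y, np.full(100, y.mean()), n_params=1)
        assert row.r2 == pytest.approx(0.0, abs=1e-12)

    def test_two_pass_rmse_mae_agreement(self):
        """Independent naive loops must reproduce the vectorized metrics."""
        rng = np.random.default_rng(1)
        y, yhat = rng.normal(size=200), rng.normal(size=200)
        row = compute_metrics(y, yhat, n_params=3)
        rmse = math.sqrt(sum((a - b) ** 2 for a, b in zip(y, yhat)) / 200)
        mae = sum(abs(a - b) for a, b in zip(y, yhat)) / 200
        assert row.rmse == pytest.approx(rmse, abs=1e-12)
        assert row.mae == pytest.approx(mae, abs=1e-12)

    def test_information_criteria_definitions(self):
        rng = np.random.default_rng(2)
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        k = 4 + 1
        row = compute_metrics(y, yhat, n_params=4)
        rss = float(np.sum((y - yhat) ** 2))
        loglik = -25.0 * (math.log(2 * math.pi * rss / 50) + 1)
        assert row.aic == pytest.approx(-2 * loglik + 2 * k, abs=1e-10)
        assert row.bic == pytest.approx(-2 * loglik + k * math.log(50), abs=1e-10)
        assert row.aicc == pytest.approx(row.aic + 2 * k * (k + 1) / (50 - k - 1), abs=1e-10)
        assert row.aicc >= row.aic

    def test_aic_ordering_invariant_to_shared_k(self):
        """With equal n_params, AIC ranking must equal RMSE ranking."""
        rng = np.random.default_rng(3)
        y = rng.normal(size=120)
        good = compute_metrics(y, y + rng.normal(0, 0.5, 120), n_params=3)
        bad = compute_metrics(y, y + rng.normal(0, 2.0, 120), n_params=3)
        assert (good.rmse < bad.rmse) == (good.aic < bad.aic)

    def test_undefined_aicc_strictness(self):
        y = np.arange(5.0)
        with pytest.raises(ValueError):
            compute_metrics(y, y + 1, n_params=4)  # n=5 <= k+1=6
        row = compute_metrics(y, y + 1, n_params=4, strict=False)
        assert row.aicc == float("inf")
        assert math.isnan(row.adj_r2)

    def test_percent_reduction_worked_examples(self):
        assert percent_rmse_reduction(15.956, 86.289) == 81.5
        assert percent_rmse_reduction(15.956, 61.516) == 74.1
        assert percent_rmse_reduction(7.3, 7.3) == 0.0
        with pytest.raises(ValueError):
            percent_rmse_reduction(1.0, 0.0)


class TestErrorSamples:
    def test_equal_absolute_residuals_give_constant_bootstrap_rmse(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        yhat = y + np.array([2.0, -2.0, 2.0, -2.0])
        s = error_samples(yhat, y, method="bayesian_bootstrap", S=50, seed=0)
        np.testing.assert_allclose(s.rmse, 2.0, atol=1e-12)
        np.testing.assert_allclose(s.mae, 2.0, atol=1e-12)

    def test_identical_posterior_draws_reduce_to_plugin(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=30)
        pred = y + rng.normal(0, 1, 30)
        mat = np.tile(pred, (20, 1))
        s = error_samples(mat, y, method="posterior_draws")
        plug = float(np.sqrt(np.mean((y - pred) ** 2)))
        np.testing.assert_allclose(s.rmse, plug, atol=1e-12)

    def test_bootstrap_mean_near_plugin(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=500)
        pred = y + rng.normal(0, 1, 500)
        s = error_samples(pred, y, method="bayesian_bootstrap", S=4000, seed=1)
        plug = float(np.sqrt(np.mean((y - pred) ** 2)))
        assert abs(s.rmse.mean() - plug) / plug < 0.02

    def test_dirichlet_weights_rows_sum_to_one(self):
        W = dirichlet_weights(40, 100, seed=2)
        assert W.shape == (100, 40)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)
        assert (W > 0).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            error_samples(np.zeros(3), np.zeros(4), method="bayesian_bootstrap")
        with pytest.raises(ValueError):
            error_samples(np.zeros(3), np.zeros(3), method="jackknife")
        with pytest.raises(ValueError):
            dirichlet_weights(10, 0)


class TestDominance:
    def test_strict_dominance_pair(self):
        a = type("S", (), {"model": "a", "rmse": np.array([1.0, 2.0]), "S": 2})
        b = type("S", (), {"model": "b", "rmse": np.array([3.0, 4.0]), "S": 2})
        dom = dominance_matrix({"a": a, "b": b})
        f = dom.to_frame()
        assert f.loc["a", "b"] == 1.0
        assert f.loc["b", "a"] == 0.0

    def test_alternating_dominance_is_half(self):
        a = type("S", (), {"model": "a", "rmse": np.array([1.0, 4.0]), "S": 2})
        b = type("S", (), {"model": "b", "rmse": np.array([2.0, 3.0]), "S": 2})
        f = dominance_matrix({"a": a, "b": b}).to_frame()
        assert f.loc["a", "b"] == 0.5
        assert f.loc["b", "a"] == 0.5

    def test_matches_brute_force_loop(self):
        """Vectorized entries must equal a plain per-replicate Python loop."""
        rng = np.random.default_rng(6)
        y = rng.normal(size=60)
        preds = {t: y + rng.normal(0, s, 60)
                 for t, s in [("a", 0.5), ("b", 1.0), ("c", 2.0)]}
        samples = joint_error_samples(preds, y, S=100, seed=7)
        dom = dominance_matrix(samples).to_frame()
        for ta in preds:
            for tb in preds:
                if ta == tb:
                    continue
                wins = sum(1 for s in range(100)
                           if samples[ta].rmse[s] < samples[tb].rmse[s])
                assert dom.loc[ta, tb] == pytest.approx(wins / 100, abs=1e-12)

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=50)
        preds = {t: y + rng.normal(0, 1, 50) for t in "abcd"}
        samples = joint_error_samples(preds, y, S=200, seed=9)
        dom = dominance_matrix(samples)
        assert dom.ties == 0
        M = dom.matrix
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert M[i, j] + M[j, i] == pytest.approx(1.0, abs=1e-12)
                    assert 0.0 <= M[i, j] <= 1.0

    def test_uniformly_dominated_model(self):
        """A much noisier predictor should lose every shared replicate."""
        rng = np.random.default_rng(10)
        y = rng.normal(size=300)
        preds = {"tight": y + rng.normal(0, 0.1, 300),
                 "wild": y + rng.normal(0, 10.0, 300)}
        samples = joint_error_samples(preds, y, S=500, seed=11)
        f = dominance_matrix(samples).to_frame()
        assert f.loc["tight", "wild"] == 1.0

    def test_mismatched_replicate_counts_rejected(self):
        a = type("S", (), {"model": "a", "rmse": np.zeros(5), "S": 5})
        b = type("S", (), {"model": "b", "rmse": np.zeros(6), "S": 6})
        with pytest.raises(ValueError):
            dominance_matrix({"a": a, "b": b})


class FakePosterior:
    """Minimal posterior object exposing the diagnostics interface."""

    def __init__(self, chains, divergences=(0, 0)):
        self.params = {"theta": np.asarray(chains, dtype=float)}
        self.divergences = list(divergences)

    @property
    def n_chains(self):
        return self.params["theta"].shape[0]

    def to_arviz(self):
        import arviz as az

        return az.from_dict(posterior={"theta": self.params["theta"]})


class TestConvergence:
    def test_iid_chains_pass(self):
        rng = np.random.default_rng(12)
        post = FakePosterior(rng.normal(size=(4, 1000)), divergences=(0,) * 4)
        report = check_convergence(post)
        assert 0.99 <= report.max_rhat <= 1.01
        assert report.min_ess > 400
        assert report.passed

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(13)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        report = check_convergence(FakePosterior(chains))
        assert report.max_rhat > 1.5
        assert not report.passed

    def test_autocorrelated_chain_fails_on_ess(self):
        rng = np.random.default_rng(14)
        chains = np.empty((2, 1500))
        for c in range(2):
            x = 0.0
            for i in range(1500):
                x = 0.999 * x + math.sqrt(1 - 0.999**2) * rng.normal()
                chains[c, i] = x
        report = check_convergence(FakePosterior(chains))
        assert report.min_ess <= 400
        assert not report.passed

    def test_divergences_veto_pass(self):
        rng = np.random.default_rng(15)
        post = FakePosterior(rng.normal(size=(4, 1000)), divergences=(1, 0, 0, 0))
        assert not check_convergence(post).passed

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            check_convergence(FakePosterior(np.zeros((1, 100)), divergences=(0,)))
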