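"""Bayesian machinery: densities against independent oracles, sampler quality."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import halfnorm, norm

from growthstack.bayes import (GrowthPriorConfig, McmcConfig, fit_bayesian_linear,
                               posterior_predict)
from growthstack.bayes.fit import _growth_design
from growthstack.bayes.models import FabensModel, GompertzModel, LinearModel
from growthstack.bayes.nuts import sample_chain
from growthstack.evaluation import check_convergence
from growthstack.preprocessing import build_design_matrices, split_train_test
from conftest import GENERATIVE_BOUNDS, make_dataset


# --------------------------------------------------------------------------
# independent log-posterior evaluator built directly from scipy.stats
def oracle_logp(tag, z, L1, t, y, Xc, Xd, pr: GrowthPriorConfig):
    u, a, b, alpha = z[0], z[1], z[2], z[3]
    pc = Xc.shape[1]
    beta_k, beta_d = z[4:4 + pc], z[4 + pc:]
    sL, sobs = math.exp(a), math.exp(b)
    Linf = pr.Linf_prior_mean + u
    k = np.exp(alpha + Xc @ beta_k + (Xd @ beta_d if Xd.size else 0.0))
    if tag == "vbgm":
        yhat = Linf - (Linf - L1) * np.exp(-k * t)
    else:
        yhat = Linf * np.exp(-np.exp(-k * t))
    lp = norm.logpdf(y, yhat, sobs).sum()
    lp += norm.logpdf(Linf, pr.Linf_prior_mean, sL)
    lp += halfnorm.logpdf(sL, scale=pr.Linf_sd_scale) + a    # log-scale Jacobians
    lp += halfnorm.logpdf(sobs, scale=pr.sigma_obs_scale) + b
    lp += norm.logpdf(alpha, 0, pr.alpha_k_sd)
    lp += norm.logpdf(beta_k, 0, pr.beta_k_sd).sum()
    if beta_d.size:
        lp += norm.logpdf(beta_d, 0, pr.beta_dummies_sd).sum()
    return float(lp)


@pytest.fixture(scope="module")
def growth_inputs(small_designs):
    tr, _, _ = small_designs["partial"]
    out = {}
    for tag, cls in [("vbgm", FabensModel), ("gompertz", GompertzModel)]:
        L1, t, Xc, Xd, feats, _ = _growth_design(tr, tag)
        out[tag] = cls(L1, t, tr.y.to_numpy(float), Xc, Xd)
    return out


class TestLogPosterior:
    @pytest.mark.parametrize("tag", ["vbgm", "gompertz"])
    def test_matches_independent_oracle_at_25_points(self, growth_inputs, tag):
        m = growth_inputs[tag]
        rng = np.random.default_rng(123)
        for _ in range(25):
            z = 0.3 * rng.normal(size=m.dim)
            z[3] = math.log(0.5) + 0.3 * rng.normal()
            got, _ = m.logp_and_grad(z)
            want = oracle_logp(tag, z, m.L1, m.t, m.y, m.Xc, m.Xd, m.priors)
            assert got == pytest.approx(want, abs=1e-6)

    @pytest.mark.parametrize("tag", ["vbgm", "gompertz"])
    def test_gradients_match_finite_differences(self, growth_inputs, tag):
        m = growth_inputs[tag]
        rng = np.random.default_rng(5)
        z = m.initial_point(rng)
        z = np.concatenate([[0.4], z])  # joint layout adds the Linf offset
        _, g = m.logp_and_grad(z)
        eps = 1e-6
        for i in range(m.dim):
            zp, zm = z.copy(), z.copy()
            zp[i] += eps
            zm[i] -= eps
            fd = (m.logp_and_grad(zp)[0] - m.logp_and_grad(zm)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-4)

    @pytest.mark.parametrize("tag", ["vbgm", "gompertz"])
    def test_marginal_equals_quadrature_over_Linf(self, growth_inputs, tag):
        m = growth_inputs[tag]
        rng = np.random.default_rng(7)
        zm = m.initial_point(rng)
        lp_marg, _ = m.marginal_logp_and_grad(zm)
        # locate the Gaussian conditional of the Linf offset to center the grid
        v, s2 = math.exp(2 * zm[0]), math.exp(2 * zm[1])
        kt = np.exp(m._eta(zm[2], zm[3:])) * m.t
        c, d, _, _ = m._cd(kt)
        prec = 1 / v + float(c @ c) / s2
        mu = (m.priors.Linf_prior_mean / v + float(c @ (m.y - d)) / s2) / prec - m.priors.Linf_prior_mean
        sd = prec ** -0.5
        ref = m.logp_and_grad(np.concatenate([[mu], zm]))[0]
        val, _ = quad(lambda u: math.exp(
            min(m.logp_and_grad(np.concatenate([[u], zm]))[0] - ref, 500.0)),
            mu - 12 * sd, mu + 12 * sd, limit=200)
        assert lp_marg == pytest.approx(math.log(val) + ref, abs=1e-6)

    def test_linear_model_matches_scipy_oracle(self, rng):
        X = rng.normal(size=(60, 4))
        y = X @ np.array([1.0, -2.0, 0.0, 0.5]) + rng.normal(0, 1, 60)
        m = LinearModel(X, y)
        for _ in range(25):
            z = 0.5 * rng.normal(size=m.dim)
            got, _ = m.logp_and_grad(z)
            beta0, beta, b = z[0], z[1:-1], z[-1]
            want = (norm.logpdf(y, beta0 + X @ beta, math.exp(b)).sum()
                    + norm.logpdf(beta0, 0, 5) + norm.logpdf(beta, 0, 5).sum()
                    + norm.logpdf(b, 0, 1))
            assert got == pytest.approx(float(want), abs=1e-6)


class TestSampler:
    def test_standard_normal_moments(self):
        def lg(z):
            return -0.5 * float(z @ z), -z
        res = sample_chain(lg, np.zeros(4), 400, 1500, np.random.default_rng(0))
        assert res.divergences == 0
        np.testing.assert_allclose(res.draws.mean(axis=0), 0.0, atol=0.12)
        np.testing.assert_allclose(res.draws.var(axis=0), 1.0, atol=0.2)

    def test_adapts_to_badly_scaled_target(self):
        sd = np.array([0.01, 1.0, 100.0])
        def lg(z):
            return -0.5 * float((z / sd) @ (z / sd)), -z / sd**2
        res = sample_chain(lg, np.zeros(3), 400, 1000, np.random.default_rng(1))
        np.testing.assert_allclose(res.draws.std(axis=0), sd, rtol=0.35)

    def test_nonfinite_start_rejected(self):
        def lg(z):
            return -np.inf, np.zeros_like(z)
        with pytest.raises(ValueError):
            sample_chain(lg, np.zeros(2), 10, 10, np.random.default_rng(0))


class TestGrowthFit:
    def test_convergence_and_recovery(self, vbgm_posterior, small_designs):
        truth = small_designs["truth"]
        report = check_convergence(vbgm_posterior)
        assert report.max_rhat <= 1.02
        assert report.divergences == 0
        Linf = vbgm_posterior.stacked("Linf")
        lo, hi = np.percentile(Linf, [2.5, 97.5])
        assert lo <= truth["true_Linf"] <= hi
        assert (vbgm_posterior.stacked("sigma_obs") > 0).all()

    def test_posterior_predict_contract(self, vbgm_posterior, small_designs):
        _, te, _ = small_designs["partial"]
        mat, point = posterior_predict(vbgm_posterior, te)
        S = vbgm_posterior.n_chains * vbgm_posterior.n_draws
        assert mat.shape == (S, len(te.y))
        np.testing.assert_allclose(point, mat.mean(axis=0))
        rmse = float(np.sqrt(np.mean((te.y.to_numpy() - point) ** 2)))
        assert rmse < 3.0 * small_designs["truth"]["sigma_obs"]

    def test_degenerate_posterior_predicts_identically(self, vbgm_posterior, small_designs):
        _, te, _ = small_designs["partial"]
        import copy
        post = copy.deepcopy(vbgm_posterior)
        for name, arr in post.params.items():
            first = arr[:1, :1]
            post.params[name] = np.broadcast_to(first, arr.shape).copy()
        mat, _ = posterior_predict(post, te)
        assert np.allclose(mat, mat[0][None, :])


class TestLinearFit:
    @pytest.fixture(scope="class")
    def linear_fit(self):
        X = np.random.default_rng(3).normal(size=(400, 3))
        beta_true = np.array([3.0, -1.5, 0.0])
        y = 2.0 + X @ beta_true + np.random.default_rng(4).normal(0, 1.0, 400)
        import pandas as pd
        from growthstack.preprocessing import DesignMatrices
        design = DesignMatrices(
            Xc=pd.DataFrame(X, columns=["a", "b", "c"]),
            Xd=pd.DataFrame(index=range(400)),
            y=pd.Series(y),
        )
        post = fit_bayesian_linear(design, mcmc=McmcConfig(n_chains=2, n_tune=300, n_draws=400, seed=6))
        return post, beta_true

    def test_recovers_coefficients_within_3_posterior_sd(self, linear_fit):
        post, beta_true = linear_fit
        beta = post.stacked("beta")
        err = np.abs(beta.mean(axis=0) - beta_true)
        assert (err <= 3.0 * beta.std(axis=0) + 1e-9).all()
        assert check_convergence(post).max_rhat <= 1.02

    def test_null_response_shrinks_to_zero(self):
        import pandas as pd
        from growthstack.preprocessing import DesignMatrices
        X = np.random.default_rng(8).normal(size=(1000, 3))
        design = DesignMatrices(
            Xc=pd.DataFrame(X, columns=list("abc")),
            Xd=pd.DataFrame(index=range(1000)),
            y=pd.Series(np.zeros(1000)),
        )
        post = fit_bayesian_linear(design, mcmc=McmcConfig(n_chains=2, n_tune=200, n_draws=300, seed=2))
        assert np.abs(post.stacked("beta").mean(axis=0)).max() < 0.1
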