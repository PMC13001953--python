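"""Fit the Bayesian growth and linear models and predict from posteriors."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..curves import days_to_years
from ..preprocessing import DesignMatrices, CONTINUOUS_FEATURES
from .models import FabensModel, GompertzModel, LinearModel, GrowthPriorConfig, McmcConfig
from .nuts import sample_chain

logger = logging.getLogger(__name__)

#: continuous covariates entering the k-link, per model.  L1 and time at
#: large enter the Fabens mean structurally, so the link excludes them; the
#: Gompertz mean has no L1 anchor, so L1 joins its link covariates (min-max
#: scaled by the training range, since the partial strategy leaves it in mm).
def link_features(model: str, include_l1: bool | None = None) -> list[str]:
    feats = [f for f in CONTINUOUS_FEATURES if f not in ("L1", "time_at_large")]
    use_l1 = (model == "gompertz") if include_l1 is None else include_l1
    if use_l1:
        feats = ["L1"] + feats
    return feats


@dataclass
class _PosteriorBase:
    params: dict[str, np.ndarray]        # name -> (chains, draws[, dim])
    divergences: list[int]
    step_sizes: list[float]
    mean_accept: list[float]

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter flattened across chains: (chains*draws, ...)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_arviz(self):
        import arviz as az

        return az.from_dict(posterior=self.params)

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: chain, draw, parameter, value."""
        rows = []
        for name, arr in self.params.items():
            C, D = arr.shape[:2]
            if arr.ndim == 2:
                for c in range(C):
                    rows.append(pd.DataFrame({
                        "chain": c, "draw": np.arange(D),
                        "parameter": name, "value": arr[c],
                    }))
            else:
                for j in range(arr.shape[2]):
                    for c in range(C):
                        rows.append(pd.DataFrame({
                            "chain": c, "draw": np.arange(D),
                            "parameter": f"{name}[{j}]", "value": arr[c, :, j],
                        }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class GrowthPosterior(_PosteriorBase):
    """Posterior draws for a mechanistic growth model."""

    model: str = "vbgm"                  # 'vbgm' | 'gompertz'
    link_cont: list[str] = field(default_factory=list)
    dummy_names: list[str] = field(default_factory=list)
    l1_range: tuple[float, float] | None = None   # gompertz-only internal scaling
    priors: GrowthPriorConfig = field(default_factory=GrowthPriorConfig)

    def __post_init__(self):
        bad = [c for c, d in enumerate(self.divergences) if d > 0]
        if bad:
            logger.warning("%s: divergent transitions in chains %s", self.model, bad)


@dataclass
class LinearPosterior(_PosteriorBase):
    """Posterior draws for the Bayesian linear model."""

    feature_names: list[str] = field(default_factory=list)
    model: str = "linear"


def _run_chains(model, mcmc: McmcConfig, logp_grad=None):
    seqs = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    results = []
    init_mass = model.initial_inv_mass() if hasattr(model, "initial_inv_mass") else None
    target = logp_grad or model.logp_and_grad
    for seq in seqs:
        rng = np.random.default_rng(seq)
        z0 = model.initial_point(rng)
        res = sample_chain(
            target, z0,
            n_tune=mcmc.n_tune, n_draws=mcmc.n_draws * mcmc.thin, rng=rng,
            target_accept=mcmc.target_accept, max_treedepth=mcmc.max_treedepth,
            init_inv_mass=init_mass,
        )
        if mcmc.thin > 1:
            res = replace(res, draws=res.draws[mcmc.thin - 1::mcmc.thin])
        results.append((res, rng))
    return results


def _growth_design(train: DesignMatrices, model: str, include_l1: bool | None = None):
    feats = link_features(model, include_l1)
    Xc = train.Xc[feats].to_numpy(float).copy()
    l1_range = None
    if "L1" in feats:
        j = feats.index("L1")
        lo, hi = float(Xc[:, j].min()), float(Xc[:, j].max())
        if hi > lo + 1e-9:  # only rescale when L1 is still in native units
            if hi > 1.5:
                l1_range = (lo, hi)
                Xc[:, j] = (Xc[:, j] - lo) / (hi - lo)
    L1 = train.Xc["L1"].to_numpy(float)
    t_years = days_to_years(train.Xc["time_at_large"].to_numpy(float))
    Xd = train.Xd.to_numpy(float)
    return L1, t_years, Xc, Xd, feats, l1_range


def fit_bayesian_growth(
    model: str,
    train: DesignMatrices,
    priors: GrowthPriorConfig | None = None,
    mcmc: McmcConfig | None = None,
    include_l1: bool | None = None,
) -> GrowthPosterior:
    """Sample the Bayesian Fabens or Gompertz model on a partial-scaling design.

    Time at large is converted from days to years at this single point.
    Returns posterior draws of {Linf, sigma_Linf, sigma_obs, alpha_k, beta_k,
    beta_dummies} organized chain x draw, plus sampler diagnostics.
    """
    if model not in ("vbgm", "gompertz"):
        raise ValueError(f"unknown growth model {model!r}")
    priors = priors or GrowthPriorConfig()
    mcmc = mcmc or McmcConfig()
    L1, t_years, Xc, Xd, feats, l1_range = _growth_design(train, model, include_l1)
    cls = FabensModel if model == "vbgm" else GompertzModel
    m = cls(L1, t_years, train.y.to_numpy(float), Xc, Xd, priors)
    # sample the Linf-marginalized posterior, then draw Linf exactly from its
    # Gaussian conditional for each retained draw (Rao-Blackwellized sampling)
    chains = _run_chains(m, mcmc, logp_grad=m.marginal_logp_and_grad)

    pc, pd_ = m.pc, m.pd
    raw = np.stack([c.draws for c, _ in chains])  # (C, D, marginal_dim)
    Linf = np.stack([
        np.array([m.sample_Linf(z, rng) for z in c.draws]) for c, rng in chains
    ])
    params = {
        "Linf": Linf,
        "sigma_Linf": np.exp(raw[:, :, 0]),
        "sigma_obs": np.exp(raw[:, :, 1]),
        "alpha_k": raw[:, :, 2],
        "beta_k": raw[:, :, 3 : 3 + pc],
        "beta_dummies": raw[:, :, 3 + pc :],
    }
    if pd_ == 0:
        params.pop("beta_dummies")
    return GrowthPosterior(
        params=params,
        divergences=[c.divergences for c, _ in chains],
        step_sizes=[c.step_size for c, _ in chains],
        mean_accept=[c.mean_accept for c, _ in chains],
        model=model,
        link_cont=feats,
        dummy_names=list(train.Xd.columns),
        l1_range=l1_range,
        priors=priors,
    )


def fit_bayesian_linear(train: DesignMatrices, mcmc: McmcConfig | None = None,
                        beta_sd: float = 5.0, log_sigma_sd: float = 1.0) -> LinearPosterior:
    """Sample the Bayesian linear model on a full-scaling design."""
    mcmc = mcmc or McmcConfig()
    X = train.X
    m = LinearModel(X, train.y.to_numpy(float), beta_sd=beta_sd, log_sigma_sd=log_sigma_sd)
    chains = _run_chains(m, mcmc)
    raw = np.stack([c.draws for c, _ in chains])
    params = {
        "beta0": raw[:, :, 0],
        "beta": raw[:, :, 1 : m.p + 1],
        "sigma": np.exp(raw[:, :, -1]),
    }
    return LinearPosterior(
        params=params,
        divergences=[c.divergences for c, _ in chains],
        step_sizes=[c.step_size for c, _ in chains],
        mean_accept=[c.mean_accept for c, _ in chains],
        feature_names=train.feature_names,
    )


def _growth_draw_matrix(post: GrowthPosterior, test: DesignMatrices, chunk: int = 512):
    Xc = test.Xc[post.link_cont].to_numpy(float).copy()
    if post.l1_range is not None:
        j = post.link_cont.index("L1")
        lo, hi = post.l1_range
        Xc[:, j] = (Xc[:, j] - lo) / (hi - lo)
    Xd = test.Xd[post.dummy_names].to_numpy(float)
    L1 = test.Xc["L1"].to_numpy(float)
    t = days_to_years(test.Xc["time_at_large"].to_numpy(float))

    Linf = post.stacked("Linf")
    alpha = post.stacked("alpha_k")
    Bk = post.stacked("beta_k")
    Bd = post.stacked("beta_dummies") if "beta_dummies" in post.params else None
    S, n = Linf.size, L1.size
    out = np.empty((S, n))
    for s0 in range(0, S, chunk):
        s1 = min(s0 + chunk, S)
        eta = alpha[s0:s1, None] + Bk[s0:s1] @ Xc.T
        if Bd is not None and Bd.shape[1]:
            eta += Bd[s0:s1] @ Xd.T
        k = np.exp(eta)
        if post.model == "vbgm":
            out[s0:s1] = Linf[s0:s1, None] - (Linf[s0:s1, None] - L1[None, :]) * np.exp(-k * t[None, :])
        else:
            out[s0:s1] = Linf[s0:s1, None] * np.exp(-np.exp(-k * t[None, :]))
    return out


def posterior_predict(posterior, test: DesignMatrices, chunk: int = 512):
    """Evaluate the model mean at the test rows for every posterior draw.

    Returns ``(draw_matrix, point)`` where ``draw_matrix`` has shape
    (chains * draws, n_test) and ``point`` is the across-draw mean.
    """
    if isinstance(posterior, GrowthPosterior):
        mat = _growth_draw_matrix(posterior, test, chunk=chunk)
    elif isinstance(posterior, LinearPosterior):
        X = test[posterior.feature_names].to_numpy(float) if isinstance(test, pd.DataFrame) else test.X
        beta0 = posterior.stacked("beta0")
        beta = posterior.stacked("beta")
        mat = beta0[:, None] + beta @ X.T
    else:
        raise TypeError(f"unsupported posterior type {type(posterior).__name__}")
    return mat, mat.mean(axis=0)
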