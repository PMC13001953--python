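"""Model evaluation: error metrics, posterior error distributions, dominance.

Point metrics follow the machine-learning conventions (RMSE with the 1/n
denominator) plus pseudo-likelihood information criteria: residuals are
treated as Gaussian with constant variance, so

    logL = -n/2 * (ln(2*pi*RSS/n) + 1)
    AIC  = -2 logL + 2k,   AICc = AIC + 2k(k+1)/(n-k-1),   BIC = -2 logL + k ln n

with ``k = n_params + 1`` (the residual variance counts as a parameter).  For
models without a likelihood the supplied ``n_params`` is a complexity proxy
and the criteria are heuristic comparisons, not inferential quantities.

Error *distributions* come from two sources: one RMSE/MAE per posterior draw
(Bayesian models), or a Bayesian bootstrap — flat-Dirichlet observation
weights shared across all models within a replicate — which induces a joint
error distribution even for deterministic predictors.  Pairwise stochastic
dominance probabilities P(a beats b) are the fraction of shared replicates in
which model a's RMSE is strictly lower.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricsRow", "compute_metrics", "percent_rmse_reduction",
    "PosteriorErrorSamples", "dirichlet_weights", "error_samples",
    "joint_error_samples", "DominanceMatrix", "dominance_matrix",
    "ConvergenceReport", "check_convergence",
]


@dataclass
class MetricsRow:
    """One model's test-set performance summary."""

    model: str
    rmse: float
    mae: float
    r2: float
    adj_r2: float
    aic: float
    aicc: float
    bic: float
    pct_rmse_reduction: float | None
    n_params: int
    n_test: int

    def to_dict(self) -> dict:
        return {
            "model": self.model, "RMSE": self.rmse, "MAE": self.mae,
            "R2": self.r2, "AdjR2": self.adj_r2, "AIC": self.aic,
            "AICC": self.aicc, "BIC": self.bic,
            "pct_rmse_reduction": self.pct_rmse_reduction,
        }


def compute_metrics(y, yhat, n_params: int, baseline_rmse: float | None = None,
                    model: str = "", strict: bool = True) -> MetricsRow:
    """Test-set metrics and pseudo-likelihood information criteria.

    ``strict=True`` raises when AICc / adjusted R² are undefined
    (n <= k + 1); otherwise those fields are NaN/inf, which happens routinely
    when a complexity proxy (e.g. total leaf count) exceeds the sample size.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat lengths disagree")
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    n = y.size
    resid = y - yhat
    rss = float(resid @ resid)
    rmse = math.sqrt(rss / n)
    mae = float(np.mean(np.abs(resid)))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    k = n_params + 1  # count the residual variance
    loglik = -0.5 * n * (math.log(2.0 * math.pi * max(rss, 1e-300) / n) + 1.0)
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * math.log(n)
    if n > k + 1:
        aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if np.isfinite(r2) else float("nan")
    elif strict:
        raise ValueError(f"AICc/adjusted R2 undefined: n={n} <= k+1={k + 1}")
    else:
        aicc, adj_r2 = float("inf"), float("nan")
    pct = percent_rmse_reduction(rmse, baseline_rmse) if baseline_rmse is not None else None
    return MetricsRow(model=model, rmse=rmse, mae=mae, r2=r2, adj_r2=adj_r2,
                      aic=aic, aicc=aicc, bic=bic, pct_rmse_reduction=pct,
                      n_params=n_params, n_test=n)


def percent_rmse_reduction(rmse_model: float, rmse_baseline: float) -> float:
    """Error reduction relative to a baseline, in percent to one decimal."""
    if rmse_baseline <= 0:
        raise ValueError("baseline RMSE must be positive")
    return round(100.0 * (rmse_baseline - rmse_model) / rmse_baseline, 1)


@dataclass
class PosteriorErrorSamples:
    """Samples of a model's test-set RMSE (and MAE) over shared replicates."""

    model: str
    rmse: np.ndarray
    mae: np.ndarray
    source: str  # 'posterior_draws' | 'bayesian_bootstrap' | 'point'

    @property
    def S(self) -> int:
        return self.rmse.size


def dirichlet_weights(n_obs: int, S: int, seed: int = 0) -> np.ndarray:
    """Flat-Dirichlet observation weights, one row per bootstrap replicate."""
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    g = rng.standard_exponential(size=(S, n_obs))
    return g / g.sum(axis=1, keepdims=True)


def error_samples(predictions, y, method: str = "posterior_draws",
                  S: int = 4000, seed: int = 0, weights: np.ndarray | None = None,
                  model: str = "") -> PosteriorErrorSamples:
    """Distribution of test-set RMSE/MAE for one model.

    ``posterior_draws``: ``predictions`` is a (draws, n_obs) matrix; one
    RMSE/MAE per draw.  ``bayesian_bootstrap``: ``predictions`` is a point
    vector; per replicate, RMSE is the Dirichlet-weighted residual norm.
    Pass the same ``weights`` matrix for every model so replicates are joint.
    """
    y = np.asarray(y, dtype=float)
    if method == "posterior_draws":
        mat = np.atleast_2d(np.asarray(predictions, dtype=float))
        if mat.shape[1] != y.size:
            raise ValueError("prediction matrix and response disagree")
        resid = mat - y[None, :]
        rmse = np.sqrt(np.mean(resid**2, axis=1))
        mae = np.mean(np.abs(resid), axis=1)
        return PosteriorErrorSamples(model=model, rmse=rmse, mae=mae, source=method)
    if method == "bayesian_bootstrap":
        point = np.asarray(predictions, dtype=float).ravel()
        if point.size != y.size:
            raise ValueError("predictions and response disagree")
        if weights is None:
            weights = dirichlet_weights(y.size, S, seed)
        resid2 = (y - point) ** 2
        rmse = np.sqrt(weights @ resid2)
        mae = weights @ np.abs(y - point)
        return PosteriorErrorSamples(model=model, rmse=rmse, mae=mae, source=method)
    raise ValueError(f"unknown method {method!r}")


def joint_error_samples(predictions: dict[str, np.ndarray], y,
                        S: int = 4000, seed: int = 0) -> dict[str, PosteriorErrorSamples]:
    """Bayesian-bootstrap error samples with one shared weight matrix.

    Sharing the Dirichlet weights across models makes replicate s directly
    comparable between models, which is what the dominance matrix needs.
    """
    y = np.asarray(y, dtype=float)
    W = dirichlet_weights(y.size, S, seed)
    return {
        tag: error_samples(pred, y, method="bayesian_bootstrap", weights=W, model=tag)
        for tag, pred in predictions.items()
    }


@dataclass
class DominanceMatrix:
    """Pairwise P(row model's RMSE < column model's RMSE)."""

    tags: list[str]
    matrix: np.ndarray
    S: int
    ties: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.tags, columns=self.tags)


def dominance_matrix(samples: dict[str, PosteriorErrorSamples]) -> DominanceMatrix:
    """Fraction of shared replicates where model a strictly beats model b.

    All sample vectors must share the replicate index (same S from the same
    joint draw).  Ties count toward neither direction.
    """
    tags = list(samples)
    S_set = {samples[t].S for t in tags}
    if len(S_set) != 1:
        raise ValueError("all models must share the same number of replicates")
    S = S_set.pop()
    R = np.stack([samples[t].rmse for t in tags])
    m = len(tags)
    out = np.full((m, m), np.nan)
    ties = 0
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            out[i, j] = float(np.mean(R[i] < R[j]))
            if i < j:
                ties += int(np.sum(R[i] == R[j]))
    return DominanceMatrix(tags=tags, matrix=out, S=S, ties=ties)


@dataclass
class ConvergenceReport:
    """Split-R-hat, bulk/tail ESS and divergence summary for one posterior."""

    rhat: dict[str, float]
    ess_bulk: dict[str, float]
    ess_tail: dict[str, float]
    divergences: int
    passed: bool
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def min_ess(self) -> float:
        return min(min(self.ess_bulk.values()), min(self.ess_tail.values()))

    def to_dict(self) -> dict:
        return {
            "max_rhat": self.max_rhat, "min_ess": self.min_ess,
            "divergences": self.divergences, "passed": self.passed,
            "rhat": self.rhat, "ess_bulk": self.ess_bulk, "ess_tail": self.ess_tail,
        }


def check_convergence(posterior, rhat_threshold: float = 1.01,
                      ess_threshold: float = 400.0) -> ConvergenceReport:
    """arviz-based diagnostics; passes iff R-hat, ESS and divergences are clean."""
    import arviz as az

    if posterior.n_chains < 2:
        raise ValueError("split-R-hat needs at least 2 chains")
    idata = posterior.to_arviz()
    rhat_ds = az.rhat(idata, method="split")
    bulk_ds = az.ess(idata, method="bulk")
    tail_ds = az.ess(idata, method="tail")

    def flatten(ds):
        out = {}
        for name in ds.data_vars:
            vals = np.atleast_1d(np.asarray(ds[name].values, dtype=float))
            if vals.size == 1:
                out[name] = float(vals[0])
            else:
                out.update({f"{name}[{i}]": float(v) for i, v in enumerate(vals.ravel())})
        return out

    rhat = flatten(rhat_ds)
    bulk = flatten(bulk_ds)
    tail = flatten(tail_ds)
    ndiv = int(sum(posterior.divergences))
    passed = (
        max(rhat.values()) <= rhat_threshold
        and min(bulk.values()) > ess_threshold
        and min(tail.values()) > ess_threshold
        and ndiv == 0
    )
    return ConvergenceReport(rhat=rhat, ess_bulk=bulk, ess_tail=tail,
                             divergences=ndiv, passed=passed,
                             rhat_threshold=rhat_threshold, ess_threshold=ess_threshold)
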