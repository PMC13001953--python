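"""Cross-model feature importance, normalized for side-by-side comparison.

Each model family reports importance in its native currency — impurity
reduction for tree ensembles, absolute coefficients for the linear SVR,
permutation RMSE increase for kernel SVR, mean |integrated gradients| for the
network, and posterior mean |beta| on the growth-rate link for the Bayesian
models (with the structural inputs L1 and time-at-large scored by permuting
them through the posterior-mean predictor).  Values are min-max normalized to
[0, 1] within each model and averaged across models into an ``Avg`` column,
mirroring the usual importance-heatmap layout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ann import NeuralNetRegressor
from .bayes.fit import GrowthPosterior, LinearPosterior, posterior_predict
from .ml import FittedModel
from .preprocessing import DesignMatrices

logger = logging.getLogger(__name__)


def integrated_gradients(network: NeuralNetRegressor, x, baseline=None, steps: int = 64) -> np.ndarray:
    """Path-integral attribution from a baseline to the input.

    Approximates ``(x - b) * ∫ grad f(b + a (x - b)) da`` with a midpoint
    Riemann sum over ``steps`` points.  Satisfies completeness
    (sum of attributions = f(x) - f(baseline)) up to discretization error,
    and is exact for linear networks at any step count.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    b = np.zeros(x.shape[1]) if baseline is None else np.asarray(baseline, dtype=float)
    if b.shape != (x.shape[1],):
        raise ValueError("baseline dimension mismatch")
    diff = x - b[None, :]
    total = np.zeros_like(x)
    for j in range(steps):
        alpha = (j + 0.5) / steps
        total += network.input_gradients(b[None, :] + alpha * diff)
    return diff * total / steps


def permutation_importance_scores(predict_fn, X, y, n_repeats: int = 10, seed: int = 0,
                                  columns=None) -> np.ndarray:
    """Mean RMSE increase when each feature column is shuffled."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    base = float(np.sqrt(np.mean((y - predict_fn(X)) ** 2)))
    cols = range(X.shape[1]) if columns is None else columns
    out = np.zeros(X.shape[1])
    for j in cols:
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas.append(float(np.sqrt(np.mean((y - predict_fn(Xp)) ** 2))) - base)
        out[j] = float(np.mean(deltas))
    return out


def _growth_posterior_importance(post: GrowthPosterior, test: DesignMatrices, y,
                                 n_repeats: int = 10, seed: int = 0) -> dict[str, float]:
    """Posterior mean |beta_k| per link covariate + permutation for L1 / t."""
    out = {}
    bk = np.abs(post.stacked("beta_k")).mean(axis=0)
    for name, val in zip(post.link_cont, bk):
        out[name] = float(val)
    structural = ["time_at_large"]
    if "L1" not in post.link_cont:
        structural.append("L1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    _, base_pred = posterior_predict(post, test)
    base = float(np.sqrt(np.mean((y - base_pred) ** 2)))
    for name in structural:
        deltas = []
        for _ in range(n_repeats):
            shuffled = test.Xc.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            perturbed = DesignMatrices(Xc=shuffled, Xd=test.Xd, y=test.y, ids=test.ids)
            _, pred = posterior_predict(post, perturbed)
            deltas.append(float(np.sqrt(np.mean((y - pred) ** 2))) - base)
        out[name] = float(np.mean(deltas))
    return out


def model_importance(model, feature_names=None, X_test=None, y_test=None,
                     n_repeats: int = 10, seed: int = 0, ig_steps: int = 64,
                     test_design: DesignMatrices | None = None) -> dict[str, float]:
    """Raw (pre-normalization) importance per feature for one fitted model.

    Tree ensembles use impurity importances, linear SVR absolute coefficients,
    kernel SVR permutation importance, the network mean |integrated gradients|
    over the test rows, and Bayesian posteriors coefficient magnitudes (plus
    permutation for inputs that enter the mean structurally).
    """
    if isinstance(model, GrowthPosterior):
        if test_design is None or y_test is None:
            raise ValueError("growth-posterior importance needs test_design and y_test")
        return _growth_posterior_importance(model, test_design, y_test,
                                            n_repeats=n_repeats, seed=seed)
    if isinstance(model, LinearPosterior):
        beta = np.abs(model.stacked("beta")).mean(axis=0)
        return dict(zip(model.feature_names, beta.tolist()))

    if not isinstance(model, FittedModel):
        raise TypeError(f"cannot score importance for {type(model).__name__}")
    names = list(feature_names or model.feature_names)
    est = model.estimator
    if model.model in ("random_forest", "xgboost", "lightgbm"):
        vals = np.asarray(est.feature_importances_, dtype=float)
    elif model.model == "svr_linear":
        vals = np.abs(np.asarray(est.coef_, dtype=float)).ravel()
    elif model.model == "svr_kernel":
        if X_test is None or y_test is None:
            raise ValueError("permutation importance needs X_test and y_test")
        vals = permutation_importance_scores(
            lambda X: np.asarray(est.predict(X)).ravel(), X_test, y_test,
            n_repeats=n_repeats, seed=seed)
    elif model.model == "ann":
        if X_test is None:
            raise ValueError("integrated gradients need X_test")
        attr = integrated_gradients(est, X_test, steps=ig_steps)
        vals = np.mean(np.abs(attr), axis=0)
    else:
        raise ValueError(f"no importance rule for {model.model!r}")
    if len(names) != vals.size:
        raise ValueError("feature name count does not match importance vector")
    return dict(zip(names, vals.tolist()))


def normalize_and_aggregate(raw: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Min-max normalize importances per model and average across models.

    Returns a features x (models + 'Avg') table on [0, 1].  Features absent
    from a model count as 0; a model whose raw values are all equal carries no
    ranking information and is set to all-zero (logged).
    """
    if not raw:
        raise ValueError("no importances supplied")
    features = sorted({f for d in raw.values() for f in d})
    table = pd.DataFrame(0.0, index=features, columns=list(raw))
    for m, d in raw.items():
        col = np.array([d.get(f, 0.0) for f in features], dtype=float)
        lo, hi = col.min(), col.max()
        if hi > lo:
            table[m] = (col - lo) / (hi - lo)
        else:
            logger.warning("model %s has constant importances; normalized to 0", m)
            table[m] = 0.0
    table["Avg"] = table[list(raw)].mean(axis=1)
    return table.sort_values("Avg", ascending=False)
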