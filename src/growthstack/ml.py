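"""Tuned machine-learning predictors: RF, XGBoost, LightGBM, SVR, ANN.

Each model family is tuned by randomized search over a fixed candidate grid
with k-fold cross-validation on the training split only, then refit on the
full training data.  The tree and kernel learners are the established
scikit-learn / xgboost / lightgbm implementations; the contribution here is
the seeded search protocol, the scoring conventions (negative MSE everywhere
except the linear SVR, which is scored by negative RMSE), and the complexity
accounting used later for pseudo-likelihood information criteria.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from xgboost import XGBRegressor
from lightgbm import LGBMRegressor

from .ann import AnnArchitecture, NeuralNetRegressor

logger = logging.getLogger(__name__)

#: candidate grids for each model family
DEFAULT_SEARCH_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {
        "n_estimators": [100, 200, 300, 400],
        "max_depth": [15, 25, None],
        "min_samples_split": [2, 5, 10],
        "min_samples_leaf": [1, 3, 5],
        "max_features": ["sqrt", "log2"],
    },
    "xgboost": {
        "eta": [0.05, 0.1, 0.15, 0.2],
        "max_depth": [3, 4, 5],
        "n_estimators": [200, 400, 600, 800],
        "subsample": [0.7, 0.8, 0.9],
        "colsample_bytree": [0.8, 0.9, 1.0],
        "reg_alpha": [0, 0.1],
        "reg_lambda": [1, 1.5],
    },
    "lightgbm": {
        "n_estimators": [100, 150, 200],
        "learning_rate": [0.05, 0.1, 0.15],
        "max_depth": [15, 20, -1],
        "num_leaves": [31, 50, 100],
        "subsample": [0.7, 0.8, 0.9],
        "colsample_bytree": [0.8, 0.9, 1.0],
        "reg_alpha": [0, 0.1],
        "reg_lambda": [0, 0.1, 1],
    },
    "svr_linear": {
        "C": [0.1, 1, 10, 100],
        "epsilon": [0.01, 0.1, 0.5],
    },
    "svr_kernel": {
        "kernel": ["linear", "poly", "rbf"],
        "C": [0.1, 1, 10, 100],
        "epsilon": [0.01, 0.1, 0.5],
        "gamma": ["scale", 0.01, 0.1],
    },
    "ann": {
        "hidden_sizes": [(256, 128, 64), (128, 64, 32), (64, 32, 16)],
        "dropout_rates_scale": [1.0, 0.5],
        "learning_rate": [5e-4, 1e-3],
        "weight_decay": [5e-5, 1e-4],
        "batch_size": [32, 64],
    },
}

#: sampled configurations per family
DEFAULT_N_ITER = {
    "random_forest": 25,
    "xgboost": 25,
    "lightgbm": 20,
    "svr_linear": 12,   # whole 4x3 grid
    "svr_kernel": 20,
    "ann": 5,
}


@dataclass
class SearchSpace:
    """Candidate grid plus the randomized-search protocol parameters."""

    grid: dict[str, list]
    n_iter: int
    cv_folds: int = 5
    scoring: str = "neg_mse"  # or 'neg_rmse'
    seed: int = 0

    def __post_init__(self):
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("every candidate list must be non-empty")
        if self.scoring not in ("neg_mse", "neg_rmse"):
            raise ValueError(f"unknown scoring {self.scoring!r}")

    @property
    def size(self) -> int:
        return int(np.prod([len(v) for v in self.grid.values()]))

    def enumerate(self) -> list[dict]:
        keys = list(self.grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(self.grid[k] for k in keys))]


def default_search_space(model: str, seed: int = 0) -> SearchSpace:
    scoring = "neg_rmse" if model == "svr_linear" else "neg_mse"
    return SearchSpace(
        grid={k: list(v) for k, v in DEFAULT_SEARCH_GRIDS[model].items()},
        n_iter=DEFAULT_N_ITER[model],
        scoring=scoring,
        seed=seed,
    )


def build_estimator(model: str, params: dict, seed: int = 0, input_dim: int | None = None,
                    ann_epochs: int = 200):
    """Instantiate an unfitted estimator for one model family."""
    params = dict(params)
    if model == "random_forest":
        return RandomForestRegressor(**params, random_state=seed, n_jobs=1)
    if model == "xgboost":
        params["learning_rate"] = params.pop("eta", params.get("learning_rate", 0.1))
        return XGBRegressor(**params, random_state=seed, n_jobs=1, verbosity=0,
                            tree_method="hist", objective="reg:squarederror")
    if model == "lightgbm":
        return LGBMRegressor(**params, random_state=seed, n_jobs=1, verbose=-1)
    if model == "svr_linear":
        return SVR(kernel="linear", **params)
    if model == "svr_kernel":
        return SVR(**params)
    if model == "ann":
        if input_dim is None:
            raise ValueError("ann needs input_dim")
        scale = params.pop("dropout_rates_scale", 1.0)
        hidden = tuple(params.pop("hidden_sizes", (256, 128, 64)))
        base_dropout = params.pop("dropout_rates", (0.4, 0.3, 0.2))
        dropout = tuple(np.round(np.asarray(base_dropout[: len(hidden)]) * scale, 3))
        arch = AnnArchitecture(input_dim=input_dim, hidden_sizes=hidden,
                               dropout_rates=dropout, epochs=ann_epochs, **params)
        return NeuralNetRegressor(arch, seed=seed)
    raise ValueError(f"unknown model family {model!r}")


@dataclass
class FittedModel:
    """A tuned and refit predictor plus its search trace."""

    model: str
    params: dict
    estimator: Any
    cv_results: list[dict] = field(default_factory=list)
    seed: int = 0
    feature_names: list[str] = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float))).ravel()


def _cv_score(model, params, X, y, folds, scoring, seed, ann_epochs):
    scores = []
    for tr_idx, va_idx in folds:
        est = build_estimator(model, params, seed=seed, input_dim=X.shape[1], ann_epochs=ann_epochs)
        est.fit(X[tr_idx], y[tr_idx])
        pred = np.asarray(est.predict(X[va_idx])).ravel()
        mse = float(np.mean((y[va_idx] - pred) ** 2))
        scores.append(-math.sqrt(mse) if scoring == "neg_rmse" else -mse)
    return float(np.mean(scores))


def random_search_tune(model: str, space: SearchSpace, X, y,
                       ann_epochs: int = 200, feature_names=None) -> FittedModel:
    """Randomized hyperparameter search with k-fold CV, refit on full train.

    Samples ``n_iter`` distinct configurations (or the whole grid when it is
    smaller), scores each by cross-validation on the training data only, picks
    the configuration with the best mean score (first sampled wins ties), and
    refits it on all training rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(space.seed)
    all_configs = space.enumerate()
    if space.n_iter >= len(all_configs):
        if space.n_iter > len(all_configs):
            logger.info("%s: n_iter %d exceeds grid size %d; evaluating all",
                        model, space.n_iter, len(all_configs))
        sampled = all_configs
    else:
        idx = rng.choice(len(all_configs), size=space.n_iter, replace=False)
        sampled = [all_configs[i] for i in idx]

    kf = KFold(n_splits=space.cv_folds, shuffle=True, random_state=space.seed)
    folds = list(kf.split(X))
    results = []
    for params in sampled:
        score = _cv_score(model, params, X, y, folds, space.scoring, space.seed, ann_epochs)
        results.append({"params": params, "mean_score": score})
    best = max(range(len(results)), key=lambda i: results[i]["mean_score"])
    best_params = results[best]["params"]
    est = build_estimator(model, best_params, seed=space.seed, input_dim=X.shape[1],
                          ann_epochs=ann_epochs)
    est.fit(X, y)
    return FittedModel(model=model, params=best_params, estimator=est,
                       cv_results=results, seed=space.seed,
                       feature_names=list(feature_names) if feature_names is not None else [])


def fit_predict(fitted: FittedModel, X_test) -> np.ndarray:
    """Deterministic test-set predictions from a fitted model."""
    X_test = np.asarray(X_test, dtype=float)
    if fitted.feature_names and X_test.shape[1] != getattr(fitted.estimator, "n_features_in_", X_test.shape[1]):
        raise ValueError("test schema does not match training schema")
    return fitted.predict(X_test)


def model_complexity(fitted: FittedModel) -> int:
    """Effective parameter count used in pseudo-likelihood penalties.

    Heuristic by family: total leaf count for tree ensembles, trainable
    parameter count for the network, support-vector count (+ intercept) for
    SVR.  These proxies make the information criteria comparable across
    paradigms but are not counts of free likelihood parameters.
    """
    est = fitted.estimator
    if fitted.model == "random_forest":
        return int(sum(tree.get_n_leaves() for tree in est.estimators_))
    if fitted.model == "xgboost":
        dump = est.get_booster().get_dump()
        return int(sum(tree.count("leaf=") for tree in dump))
    if fitted.model == "lightgbm":
        info = est.booster_.dump_model()
        return int(sum(t["num_leaves"] for t in info["tree_info"]))
    if fitted.model in ("svr_linear", "svr_kernel"):
        return int(est.support_.size + 1)
    if fitted.model == "ann":
        return int(est.n_parameters)
    raise ValueError(f"unknown model family {fitted.model!r}")
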