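"""Model combination: stacked meta-learning and pseudo-Bayesian model averaging.

The stacked ensemble fits a linear meta-learner (ordinary least squares with
intercept) on out-of-fold base-model predictions, so the meta weights are
never informed by rows the base models saw during their own training.

Pseudo-BMA forms simplex weights from model-comparison criteria: for
information criteria ``w_m ∝ exp(-Δ_m / 2)`` with Δ taken from the minimum;
for cross-validated log scores ``w_m ∝ exp(score_m - max)``.  Predictions are
the weight-averaged member predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .preprocessing import DesignMatrices

logger = logging.getLogger(__name__)


def make_oof_predictions(bases: dict, designs: dict, folds: int = 5, seed: int = 0) -> pd.DataFrame:
    """Out-of-fold predictions for each base learner.

    ``bases`` maps tag -> learner with ``fit(design)`` and ``predict(design)``
    methods; ``designs`` maps tag -> the (row-aligned) training design that
    learner uses.  Every row is predicted exactly once, by a model fit on the
    other folds, so the meta-learner sees no leakage.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    tags = list(bases)
    n = len(next(iter(designs.values())).y)
    if any(len(designs[t].y) != n for t in tags):
        raise ValueError("base designs are not row-aligned")
    if n < 2 * folds:
        raise ValueError("too few rows for the requested fold count")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = pd.DataFrame(index=next(iter(designs.values())).ids, columns=tags, dtype=float)
    for tr_pos, va_pos in kf.split(np.arange(n)):
        for tag in tags:
            design = designs[tag]
            learner = bases[tag]
            learner.fit(design.take(tr_pos))
            oof.iloc[va_pos, oof.columns.get_loc(tag)] = learner.predict(design.take(va_pos))
    return oof


@dataclass
class StackedModel:
    """Linear meta-learner over base-model predictions."""

    base_tags: list[str]
    intercept: float
    weights: np.ndarray
    oof: pd.DataFrame | None = None

    def predict(self, base_predictions) -> np.ndarray:
        """Combine base predictions (DataFrame or dict keyed by tag)."""
        if isinstance(base_predictions, dict):
            P = np.column_stack([np.asarray(base_predictions[t], dtype=float) for t in self.base_tags])
        else:
            P = base_predictions[self.base_tags].to_numpy(float)
        return self.intercept + P @ self.weights


def fit_stack(oof: pd.DataFrame, y, ridge_fallback: float = 1e-6) -> StackedModel:
    """Ordinary least squares of the response on out-of-fold base predictions.

    Near-collinear base columns trigger a small-ridge fallback, logged.
    """
    y = np.asarray(y, dtype=float)
    P = oof.to_numpy(float)
    if P.shape[0] != y.size:
        raise ValueError("OOF rows and response length disagree")
    A = np.column_stack([np.ones(len(y)), P])
    cond = np.linalg.cond(A)
    if cond > 1e10:
        logger.warning("collinear base predictions (cond=%.2g); ridge fallback", cond)
        AtA = A.T @ A + ridge_fallback * np.eye(A.shape[1])
        coef = np.linalg.solve(AtA, A.T @ y)
    else:
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return StackedModel(base_tags=list(oof.columns), intercept=float(coef[0]),
                        weights=coef[1:], oof=oof)


@dataclass
class EnsembleWeights:
    """Simplex weights over candidate models plus the criterion that produced them."""

    weights: dict[str, float]
    criterion: str = "information_criterion"

    def __post_init__(self):
        vals = np.array(list(self.weights.values()))
        if np.any(vals < -1e-12) or abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")


def pseudo_bma_weights(criteria: dict[str, float],
                       mode: str = "information_criterion") -> EnsembleWeights:
    """Approximate posterior model probabilities from comparison criteria.

    ``information_criterion`` mode expects AIC-like values (smaller better):
    ``w ∝ exp(-(c - min)/2)``.  ``cv_logscore`` mode expects mean predictive
    log scores (larger better): ``w ∝ exp(c - max)``.
    """
    finite = {m: c for m, c in criteria.items() if np.isfinite(c)}
    if len(finite) < 2:
        raise ValueError("need at least two models with finite criteria")
    tags = list(finite)
    c = np.array([finite[m] for m in tags], dtype=float)
    if mode == "information_criterion":
        logw = -0.5 * (c - c.min())
    elif mode == "cv_logscore":
        logw = c - c.max()
    else:
        raise ValueError(f"unknown pseudo-BMA mode {mode!r}")
    w = np.exp(logw)
    w /= w.sum()
    return EnsembleWeights(weights=dict(zip(tags, w.tolist())), criterion=mode)


def bma_predict(weights: EnsembleWeights, predictions: dict[str, np.ndarray],
                draws: dict[str, np.ndarray] | None = None,
                n_mixture_draws: int | None = None, seed: int = 0):
    """Weight-averaged point predictions, optionally with mixture draws.

    ``predictions`` maps tag -> point prediction vector.  If ``draws`` maps
    tags to (n_draws, n_obs) matrices, a posterior mixture is sampled: each
    mixture draw picks a member model with probability equal to its weight and
    a uniformly chosen posterior draw from that member (deterministic members
    contribute their point prediction).
    """
    missing = [m for m in weights.weights if m not in predictions]
    if missing:
        raise KeyError(f"missing predictions for {missing}")
    tags = list(weights.weights)
    w = np.array([weights.weights[t] for t in tags])
    P = np.stack([np.asarray(predictions[t], dtype=float) for t in tags])
    point = w @ P
    if draws is None:
        return point
    rng = np.random.default_rng(seed)
    S = n_mixture_draws or max(d.shape[0] for d in draws.values() if d is not None)
    n = P.shape[1]
    out = np.empty((S, n))
    members = rng.choice(len(tags), size=S, p=w)
    for s, mi in enumerate(members):
        tag = tags[mi]
        d = draws.get(tag)
        if d is None:
            out[s] = predictions[tag]
        else:
            out[s] = d[rng.integers(d.shape[0])]
    return point, out
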