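"""Refittable learner adapters with a common fit(design)/predict(design) API.

The stacking stage needs base models it can refit on cross-validation folds.
Bayesian growth models consume a partial-scaling design (native-unit L1 and
time at large); machine-learning models consume the flattened full-scaling
matrix.  These thin adapters hide that difference behind one protocol.
"""

from __future__ import annotations

import numpy as np

from .bayes import GrowthPriorConfig, McmcConfig, fit_bayesian_growth, posterior_predict
from .ml import build_estimator
from .preprocessing import DesignMatrices


class MlLearner:
    """Wraps an sklearn-style estimator family with fixed hyperparameters."""

    def __init__(self, family: str, params: dict, seed: int = 0, ann_epochs: int = 200):
        self.family = family
        self.params = dict(params)
        self.seed = seed
        self.ann_epochs = ann_epochs
        self.estimator = None

    def fit(self, design: DesignMatrices):
        X = design.X
        self.estimator = build_estimator(self.family, self.params, seed=self.seed,
                                         input_dim=X.shape[1], ann_epochs=self.ann_epochs)
        self.estimator.fit(X, design.y.to_numpy(float))
        return self

    def predict(self, design: DesignMatrices) -> np.ndarray:
        if self.estimator is None:
            raise RuntimeError("learner is not fitted")
        return np.asarray(self.estimator.predict(design.X)).ravel()


class BayesianGrowthLearner:
    """Refittable Bayesian growth model predicting with the posterior mean."""

    def __init__(self, model: str = "vbgm", priors: GrowthPriorConfig | None = None,
                 mcmc: McmcConfig | None = None):
        self.model = model
        self.priors = priors or GrowthPriorConfig()
        self.mcmc = mcmc or McmcConfig(n_chains=2, n_tune=250, n_draws=500)
        self.posterior = None

    def fit(self, design: DesignMatrices):
        self.posterior = fit_bayesian_growth(self.model, design, priors=self.priors,
                                             mcmc=self.mcmc)
        return self

    def predict(self, design: DesignMatrices) -> np.ndarray:
        if self.posterior is None:
            raise RuntimeError("learner is not fitted")
        _, point = posterior_predict(self.posterior, design)
        return point
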