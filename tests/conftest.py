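"""Shared fixtures: small synthetic datasets and pre-fit posteriors.

Everything is generated programmatically and seeded, so the suite needs no
data files.  The heavier fixtures (an MCMC fit, a trained network) are
session-scoped and shared across test modules.
"""

import warnings

import numpy as np
import pytest

from growthstack.bayes import McmcConfig, fit_bayesian_growth
from growthstack.preprocessing import build_design_matrices, split_train_test
from growthstack.synthetic import (DEFAULT_COVARIATE_MOMENTS, SimulationConfig,
                                   generate_dataset)

warnings.filterwarnings("ignore", message=".*ArviZ.*")

GENERATIVE_BOUNDS = {k: (v[2], v[3]) for k, v in DEFAULT_COVARIATE_MOMENTS.items()}


def make_dataset(n=400, seed=42, sigma_obs=5.0, date_range=(2019, 2020), **kw):
    cfg = SimulationConfig(n_fish=n, seed=seed, sigma_obs=sigma_obs,
                           date_range=date_range, **kw)
    df, truth = generate_dataset(cfg)
    return df, truth, cfg


@pytest.fixture(scope="session")
def small_data():
    """400 records over two years, observation noise 5 mm."""
    return make_dataset()


@pytest.fixture(scope="session")
def small_designs(small_data):
    """Partial- and full-scaling train/test designs for the small dataset.

    Continuous covariates are scaled by the generative bounds so fitted link
    coefficients live on the same scale as the simulation truth.
    """
    df, truth, cfg = small_data
    train, test = split_train_test(df, 0.7, seed=7)
    partial = build_design_matrices(train, test, strategy="partial", bounds=GENERATIVE_BOUNDS)
    full = build_design_matrices(train, test, strategy="full", bounds=GENERATIVE_BOUNDS)
    return {"partial": partial, "full": full, "truth": truth, "train": train, "test": test}


@pytest.fixture(scope="session")
def vbgm_posterior(small_designs):
    """A converged Bayesian Fabens fit shared across test modules."""
    tr, te, _ = small_designs["partial"]
    post = fit_bayesian_growth(
        "vbgm", tr, mcmc=McmcConfig(n_chains=2, n_tune=400, n_draws=500, seed=11))
    return post


@pytest.fixture
def rng():
    return np.random.default_rng(0)
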