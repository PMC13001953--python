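"""Pipeline configuration: YAML schema, defaults, validation.

An empty config is valid — every key has a default reproducing the study
conditions (9,798 simulated records, 70/30 split, 5-fold CV, the printed
hyperparameter grids, 4 NUTS chains with 500 tuning + 1,000 posterior draws
at target acceptance 0.95).  Unknown keys are rejected with an error listing
them, so typos fail loudly.
"""

from __future__ import annotations

import copy
from dataclasses import asdict

import yaml

from .bayes.models import GrowthPriorConfig, McmcConfig

ALL_MODELS = (
    "baseline_vbgm", "baseline_gompertz",
    "bayesian_vbgm", "bayesian_gompertz", "bayesian_linear",
    "random_forest", "xgboost", "lightgbm",
    "svr_linear", "svr_kernel", "ann",
)

DEFAULTS: dict = {
    "seed": 0,
    "split_ratio": 0.7,
    "cv_folds": 5,
    "scaling": {
        # min-max bounds come from the training split; 'generative' pins them
        # to the simulation's configured covariate bounds instead, so fitted
        # link coefficients share the truth's parameterization
        "bounds": "train",  # 'train' | 'generative'
    },
    "simulate": {},  # SimulationConfig overrides (n_fish, sigma_obs, ...)
    "models": list(ALL_MODELS),
    "mcmc": {"n_chains": 4, "n_tune": 500, "n_draws": 1000, "target_accept": 0.95,
             "max_treedepth": 10, "thin": 1},
    "oof_mcmc": {"n_chains": 2, "n_tune": 250, "n_draws": 500, "target_accept": 0.95,
                 "max_treedepth": 10, "thin": 1},
    "priors": {k: v for k, v in asdict(GrowthPriorConfig()).items()},
    "search": {
        "n_iter": {},       # per-family overrides of the sampled-config counts
        "grids": {},        # per-family grid overrides
    },
    "ann_epochs": 200,
    "ensembles": {
        "stack": {"bases": ["bayesian_vbgm", "xgboost"], "folds": 5},
        "bma": {"criterion": "information_criterion", "members": None},
    },
    "evaluation": {"bootstrap_S": 4000},
    "importance": {"n_repeats": 10, "ig_steps": 64},
}


class ConfigError(ValueError):
    """Raised with the full list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


def _merge(defaults, override, path, errors):
    out = copy.deepcopy(defaults)
    for key, val in (override or {}).items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            errors.append(f"unknown key {where!r}")
            continue
        if isinstance(defaults[key], dict) and key not in ("simulate", "grids", "n_iter"):
            if not isinstance(val, dict):
                errors.append(f"{where!r} must be a mapping")
                continue
            out[key] = _merge(defaults[key], val, where, errors)
        else:
            out[key] = val
    return out


def validate_config(raw: dict | None) -> dict:
    """Apply defaults and check ranges; raises ConfigError listing problems."""
    errors: list[str] = []
    cfg = _merge(DEFAULTS, raw or {}, "", errors)

    if not 0.0 < cfg["split_ratio"] < 1.0:
        errors.append(f"'split_ratio' must be in (0, 1), got {cfg['split_ratio']}")
    if cfg["cv_folds"] < 2:
        errors.append("'cv_folds' must be >= 2")
    if cfg["scaling"]["bounds"] not in ("train", "generative"):
        errors.append("'scaling.bounds' must be 'train' or 'generative'")
    unknown_models = [m for m in cfg["models"] if m not in ALL_MODELS]
    if unknown_models:
        errors.append(f"unknown models {unknown_models}; choose from {list(ALL_MODELS)}")
    for mkey in ("mcmc", "oof_mcmc"):
        try:
            McmcConfig(**{**cfg[mkey], "seed": 0})
        except (TypeError, ValueError) as exc:
            errors.append(f"{mkey!r}: {exc}")
    try:
        GrowthPriorConfig(**cfg["priors"])
    except (TypeError, ValueError) as exc:
        errors.append(f"'priors': {exc}")
    stack_bases = cfg["ensembles"]["stack"]["bases"]
    if len(stack_bases) < 2:
        errors.append("'ensembles.stack.bases' needs at least two base models")
    if cfg["ensembles"]["bma"]["criterion"] not in ("information_criterion", "cv_logscore"):
        errors.append("'ensembles.bma.criterion' must be 'information_criterion' or 'cv_logscore'")
    if cfg["evaluation"]["bootstrap_S"] < 1:
        errors.append("'evaluation.bootstrap_S' must be >= 1")

    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path=None) -> dict:
    """Read a YAML config file (or none) and return the validated config."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def mcmc_from_config(cfg: dict, key: str = "mcmc", seed: int = 0) -> McmcConfig:
    return McmcConfig(**{**cfg[key], "seed": seed})


def priors_from_config(cfg: dict) -> GrowthPriorConfig:
    return GrowthPriorConfig(**cfg["priors"])
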