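"""End-to-end pipeline: simulate -> preprocess -> fit -> ensemble -> evaluate -> report.

Every stage reads its inputs from, and writes its outputs to, a run directory,
so any stage can be rerun in isolation and every number in the final tables is
traceable to a stage artifact.  A manifest accumulates content digests, seeds
and wall-clock times per stage.

Artifacts (all plain text):

* simulate:   records.csv, truth.json, series.csv
* preprocess: train.csv, test.csv, scaler_full.json, scaler_partial.json
* fit:        predictions.csv (one column per model), model_meta.json,
              posterior_<m>.csv, convergence_<m>.json, error_draws_<m>.csv,
              importance_raw.json
* ensemble:   stack.json, bma.json, ensemble columns appended to predictions.csv
* evaluate:   metrics.csv (performance table), dominance.csv (pairwise
              stochastic-dominance matrix), diagnostics.json
* report:     importance.csv, importance_long.csv
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .bayes import fit_bayesian_growth, fit_bayesian_linear, posterior_predict
from .config import load_config, mcmc_from_config, priors_from_config, validate_config
from .curves import days_to_years, fit_baseline
from .ensembles import bma_predict, fit_stack, make_oof_predictions, pseudo_bma_weights
from .evaluation import (check_convergence, compute_metrics, dominance_matrix,
                         error_samples, joint_error_samples)
from .importance import model_importance, normalize_and_aggregate
from .learners import BayesianGrowthLearner, MlLearner
from .ml import default_search_space, fit_predict, model_complexity, random_search_tune, SearchSpace
from .preprocessing import build_design_matrices, split_train_test
from .synthetic import SimulationConfig, generate_dataset, generate_monthly_series

logger = logging.getLogger(__name__)

BAYESIAN_GROWTH = ("bayesian_vbgm", "bayesian_gompertz")
ML_FAMILIES = ("random_forest", "xgboost", "lightgbm", "svr_linear", "svr_kernel", "ann")


# ---------------------------------------------------------------- manifest
def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _update_manifest(outdir: Path, stage: str, files: list[Path], seconds: float, cfg: dict):
    mpath = outdir / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {
        "config_hash": hashlib.sha256(
            yaml.dump(cfg, sort_keys=True).encode()).hexdigest()[:16],
        "seed": cfg["seed"],
        "versions": _versions(),
        "stages": {},
    }
    manifest["stages"][stage] = {
        "seconds": round(seconds, 2),
        "files": {f.name: _digest(f) for f in files if f.exists()},
    }
    mpath.write_text(json.dumps(manifest, indent=2))


def _versions() -> dict:
    import lightgbm
    import sklearn
    import xgboost

    return {
        "numpy": np.__version__, "pandas": pd.__version__,
        "sklearn": sklearn.__version__, "xgboost": xgboost.__version__,
        "lightgbm": lightgbm.__version__,
    }


def _stage(name):
    def deco(fn):
        def wrapper(cfg: dict, outdir) -> list:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            t0 = time.time()
            files = fn(cfg, outdir)
            _update_manifest(outdir, name, files, time.time() - t0, cfg)
            logger.info("stage %s finished in %.1fs", name, time.time() - t0)
            return files
        wrapper.__name__ = f"stage_{name}"
        return wrapper
    return deco


# ---------------------------------------------------------------- stages
@_stage("simulate")
def stage_simulate(cfg: dict, outdir: Path):
    sim = SimulationConfig.from_dict({**cfg["simulate"], "seed": cfg["simulate"].get("seed", cfg["seed"])})
    series = generate_monthly_series(sim)
    records, truth = generate_dataset(sim, series)
    synthetic.write_dataset(records, truth, outdir / "records.csv", outdir / "truth.json")
    frames = [s.to_frame().set_index(["year", "month"]) for s in series]
    pd.concat(frames, axis=1).reset_index().to_csv(outdir / "series.csv", index=False)
    return [outdir / "records.csv", outdir / "truth.json", outdir / "series.csv"]


@_stage("preprocess")
def stage_preprocess(cfg: dict, outdir: Path):
    records = synthetic.read_dataset(outdir / "records.csv")
    train, test = split_train_test(records, ratio=cfg["split_ratio"], seed=cfg["seed"])
    train.to_csv(outdir / "train.csv", index=False)
    test.to_csv(outdir / "test.csv", index=False)
    for strategy in ("full", "partial"):
        _, _, params = build_design_matrices(train, test, strategy=strategy,
                                             bounds=_bounds(cfg, outdir))
        (outdir / f"scaler_{strategy}.json").write_text(json.dumps(params.to_dict(), indent=2))
    return [outdir / f for f in ("train.csv", "test.csv", "scaler_full.json", "scaler_partial.json")]


def _bounds(cfg: dict, outdir: Path):
    if cfg["scaling"]["bounds"] != "generative":
        return None
    truth = json.loads((outdir / "truth.json").read_text())
    return {k: (v[2], v[3]) for k, v in truth["covariate_moments"].items()}


def _load_designs(cfg: dict, outdir: Path):
    train = synthetic.read_dataset(outdir / "train.csv")
    test = synthetic.read_dataset(outdir / "test.csv")
    bounds = _bounds(cfg, outdir)
    designs = {}
    for strategy in ("full", "partial"):
        tr, te, _ = build_design_matrices(train, test, strategy=strategy, bounds=bounds)
        designs[strategy] = (tr, te)
    return designs


def _posterior_error_draws(post, test_design, path: Path):
    mat, point = posterior_predict(post, test_design)
    samples = error_samples(mat, test_design.y.to_numpy(float), method="posterior_draws")
    pd.DataFrame({"rmse": samples.rmse, "mae": samples.mae}).to_csv(path, index=False)
    return point


@_stage("fit")
def stage_fit(cfg: dict, outdir: Path):
    designs = _load_designs(cfg, outdir)
    tr_full, te_full = designs["full"]
    tr_part, te_part = designs["partial"]
    t_train = days_to_years(tr_part.Xc["time_at_large"].to_numpy(float))
    t_test = days_to_years(te_part.Xc["time_at_large"].to_numpy(float))
    priors = priors_from_config(cfg)
    mcmc = mcmc_from_config(cfg, "mcmc", seed=cfg["seed"])

    preds = pd.DataFrame(index=te_full.ids)
    meta: dict[str, dict] = {}
    raw_importance: dict[str, dict] = {}
    files = []

    for model in cfg["models"]:
        t0 = time.time()
        if model.startswith("baseline_"):
            kind = model.split("_", 1)[1]
            fit = fit_baseline(kind, t_train, tr_part.y.to_numpy(float))
            preds[model] = fit.predict(t_test)
            meta[model] = {"n_params": 2, "Linf": fit.Linf, "K": fit.K}
        elif model in BAYESIAN_GROWTH:
            kind = model.split("_", 1)[1]
            post = fit_bayesian_growth(kind, tr_part, priors=priors, mcmc=mcmc)
            point = _posterior_error_draws(post, te_part, outdir / f"error_draws_{model}.csv")
            preds[model] = point
            post.to_frame().to_csv(outdir / f"posterior_{model}.csv", index=False)
            report = check_convergence(post) if mcmc.n_chains > 1 else None
            if report is not None:
                (outdir / f"convergence_{model}.json").write_text(
                    json.dumps(report.to_dict(), indent=2))
                files += [outdir / f"convergence_{model}.json"]
            n_sampled = 4 + post.stacked("beta_k").shape[1] + (
                post.stacked("beta_dummies").shape[1] if "beta_dummies" in post.params else 0)
            meta[model] = {"n_params": n_sampled,
                           "divergences": post.divergences,
                           "Linf_mean": float(post.stacked("Linf").mean())}
            raw_importance[model] = model_importance(
                post, test_design=te_part, y_test=te_part.y.to_numpy(float),
                n_repeats=cfg["importance"]["n_repeats"], seed=cfg["seed"])
            files += [outdir / f"posterior_{model}.csv", outdir / f"error_draws_{model}.csv"]
        elif model == "bayesian_linear":
            post = fit_bayesian_linear(tr_full, mcmc=mcmc)
            preds[model] = _posterior_error_draws(post, te_full,
                                                  outdir / f"error_draws_{model}.csv")
            post.to_frame().to_csv(outdir / f"posterior_{model}.csv", index=False)
            report = check_convergence(post) if mcmc.n_chains > 1 else None
            if report is not None:
                (outdir / f"convergence_{model}.json").write_text(
                    json.dumps(report.to_dict(), indent=2))
                files += [outdir / f"convergence_{model}.json"]
            meta[model] = {"n_params": len(post.feature_names) + 2,
                           "divergences": post.divergences}
            raw_importance[model] = model_importance(post)
            files += [outdir / f"posterior_{model}.csv", outdir / f"error_draws_{model}.csv"]
        elif model in ML_FAMILIES:
            space = _search_space(cfg, model)
            fitted = random_search_tune(model, space, tr_full.X, tr_full.y.to_numpy(float),
                                        ann_epochs=cfg["ann_epochs"],
                                        feature_names=tr_full.feature_names)
            preds[model] = fit_predict(fitted, te_full.X)
            meta[model] = {"n_params": model_complexity(fitted),
                           "selected": _jsonable(fitted.params),
                           "cv_results": [{"params": _jsonable(r["params"]),
                                           "mean_score": r["mean_score"]}
                                          for r in fitted.cv_results]}
            raw_importance[model] = model_importance(
                fitted, X_test=te_full.X, y_test=te_full.y.to_numpy(float),
                n_repeats=cfg["importance"]["n_repeats"], seed=cfg["seed"],
                ig_steps=cfg["importance"]["ig_steps"])
        else:
            raise ValueError(f"unknown model {model!r}")
        logger.info("fit %s in %.1fs", model, time.time() - t0)

    preds.to_csv(outdir / "predictions.csv", index_label="row_id")
    (outdir / "model_meta.json").write_text(json.dumps(meta, indent=2))
    (outdir / "importance_raw.json").write_text(json.dumps(raw_importance, indent=2))
    return files + [outdir / "predictions.csv", outdir / "model_meta.json",
                    outdir / "importance_raw.json"]


def _jsonable(d: dict) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _search_space(cfg: dict, model: str) -> SearchSpace:
    space = default_search_space(model, seed=cfg["seed"])
    if model in cfg["search"]["grids"]:
        space.grid = {k: list(v) for k, v in cfg["search"]["grids"][model].items()}
    if model in cfg["search"]["n_iter"]:
        space.n_iter = int(cfg["search"]["n_iter"][model])
    space.cv_folds = cfg["cv_folds"]
    return space


@_stage("ensemble")
def stage_ensemble(cfg: dict, outdir: Path):
    designs = _load_designs(cfg, outdir)
    tr_full, te_full = designs["full"]
    tr_part, te_part = designs["partial"]
    preds = pd.read_csv(outdir / "predictions.csv", index_col="row_id")
    meta = json.loads((outdir / "model_meta.json").read_text())
    y_test = te_full.y.to_numpy(float)
    priors = priors_from_config(cfg)

    written = []
    # ---- stacked ensemble on out-of-fold base predictions
    stack_cfg = cfg["ensembles"]["stack"]
    missing = [t for t in stack_cfg["bases"] if t not in preds.columns]
    if missing:
        logger.warning("stack skipped: base models %s were not fitted", missing)
        stack_cfg = None
    bases, base_designs = {}, {}
    for tag in stack_cfg["bases"] if stack_cfg else []:
        if tag in BAYESIAN_GROWTH:
            kind = tag.split("_", 1)[1]
            bases[tag] = BayesianGrowthLearner(kind, priors=priors,
                                               mcmc=mcmc_from_config(cfg, "oof_mcmc", seed=cfg["seed"]))
            base_designs[tag] = tr_part
        elif tag in ML_FAMILIES:
            params = meta[tag]["selected"]
            bases[tag] = MlLearner(tag, params, seed=cfg["seed"], ann_epochs=cfg["ann_epochs"])
            base_designs[tag] = tr_full
        else:
            raise ValueError(f"stack base {tag!r} is not a supported base learner")
    if stack_cfg:
        oof = make_oof_predictions(bases, base_designs, folds=stack_cfg["folds"], seed=cfg["seed"])
        stack = fit_stack(oof, tr_full.y.to_numpy(float))
        preds["ensemble_stacked"] = stack.predict({t: preds[t].to_numpy() for t in stack.base_tags})
        meta["ensemble_stacked"] = {
            "n_params": len(stack.base_tags) + 1,
            "intercept": stack.intercept,
            "weights": dict(zip(stack.base_tags, stack.weights.tolist())),
        }
        oof.to_csv(outdir / "oof.csv", index_label="row_id")
        (outdir / "stack.json").write_text(json.dumps(meta["ensemble_stacked"], indent=2))
        written += [outdir / "oof.csv", outdir / "stack.json"]

    # ---- pseudo-BMA over individual (non-baseline) models
    bma_cfg = cfg["ensembles"]["bma"]
    members = bma_cfg["members"] or [m for m in preds.columns
                                     if not m.startswith(("baseline_", "ensemble_"))]
    members = [m for m in members if m in preds.columns]
    if len(members) >= 2:
        criteria = {}
        for m in members:
            row = compute_metrics(y_test, preds[m].to_numpy(), n_params=meta[m]["n_params"],
                                  model=m, strict=False)
            criteria[m] = row.aicc if np.isfinite(row.aicc) else row.aic
        weights = pseudo_bma_weights(criteria, mode=bma_cfg["criterion"])
        preds["ensemble_bma"] = bma_predict(weights, {m: preds[m].to_numpy() for m in weights.weights})
        meta["ensemble_bma"] = {"n_params": len(weights.weights),
                                "weights": weights.weights, "criterion": weights.criterion,
                                "criteria": criteria}
        (outdir / "bma.json").write_text(json.dumps(meta["ensemble_bma"], indent=2))
        written.append(outdir / "bma.json")
    else:
        logger.warning("pseudo-BMA skipped: fewer than two member models fitted")

    preds.to_csv(outdir / "predictions.csv", index_label="row_id")
    (outdir / "model_meta.json").write_text(json.dumps(meta, indent=2))
    return written + [outdir / "predictions.csv", outdir / "model_meta.json"]


@_stage("evaluate")
def stage_evaluate(cfg: dict, outdir: Path):
    test = synthetic.read_dataset(outdir / "test.csv")
    y = test["L2"].to_numpy(float)
    preds = pd.read_csv(outdir / "predictions.csv", index_col="row_id")
    meta = json.loads((outdir / "model_meta.json").read_text())

    baseline_rmse = None
    if "baseline_vbgm" in preds.columns:
        r = y - preds["baseline_vbgm"].to_numpy()
        baseline_rmse = float(np.sqrt(np.mean(r**2)))

    rows = []
    for m in preds.columns:
        rows.append(compute_metrics(y, preds[m].to_numpy(), n_params=meta[m]["n_params"],
                                    baseline_rmse=baseline_rmse, model=m, strict=False).to_dict())
    table = pd.DataFrame(rows).sort_values("RMSE").reset_index(drop=True)
    table.to_csv(outdir / "metrics.csv", index=False)

    samples = joint_error_samples({m: preds[m].to_numpy() for m in preds.columns}, y,
                                  S=cfg["evaluation"]["bootstrap_S"], seed=cfg["seed"])
    dom = dominance_matrix(samples)
    order = table["model"].tolist()
    dom.to_frame().loc[order, order].to_csv(outdir / "dominance.csv", index_label="model")

    diagnostics = {}
    for f in outdir.glob("convergence_*.json"):
        diagnostics[f.stem.replace("convergence_", "")] = json.loads(f.read_text())
    (outdir / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    return [outdir / f for f in ("metrics.csv", "dominance.csv", "diagnostics.json")]


@_stage("report")
def stage_report(cfg: dict, outdir: Path):
    raw = json.loads((outdir / "importance_raw.json").read_text())
    if raw:
        table = normalize_and_aggregate(raw)
        table.to_csv(outdir / "importance.csv", index_label="feature")
        long = table.reset_index(names="feature").melt(
            id_vars="feature", var_name="model", value_name="importance")
        long.to_csv(outdir / "importance_long.csv", index=False)
        return [outdir / "importance.csv", outdir / "importance_long.csv"]
    return []


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "fit": stage_fit,
    "ensemble": stage_ensemble,
    "evaluate": stage_evaluate,
    "report": stage_report,
}


def run_pipeline(config: dict | str | Path | None, outdir, seed: int | None = None) -> Path:
    """Run every stage in order; returns the run directory."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    for name, fn in STAGES.items():
        try:
            fn(cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return outdir
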