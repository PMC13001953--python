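# growthstack

Hybrid mechanistic + machine-learning growth modelling for fish
tag-recapture data.

## The problem

In a tag-recapture study each fish is measured at release (fork length
`L1`, in mm), released, and measured again at recovery (`L2`) after a
known time at large `t`. Because the fish's age is unknown, growth is
modelled directly on the increment. `growthstack` implements two
mechanistic growth curves in the tag-recapture parameterization:

- **Fabens / von Bertalanffy:** `L2 = L1 + (L∞ − L1)(1 − e^{−kt})`
- **Gompertz:** `L2 = L∞ · e^{−e^{−kt}}`

with the growth coefficient `k` linked log-linearly to environmental and
biological covariates (water temperature, discharge, solar insolation,
phosphorus concentration, biomass density, release location, seasonal and
annual indicator terms):

```
k = exp(α + Xc·β + Xd·β_ind)
```

Posteriors for `L∞`, `k`-link coefficients and observation noise come from
a built-in No-U-Turn sampler (NUTS). Alongside the mechanistic models the
package fits a Bayesian linear model and a suite of machine-learning
regressors (random forest, XGBoost, LightGBM, linear and kernel SVR, and a
residual feed-forward network), tuned by randomized search over 5-fold
cross-validation. Models are combined by a stacked linear meta-learner fit
on out-of-fold predictions and by pseudo-Bayesian model averaging, and
compared with RMSE/MAE/R², pseudo-likelihood information criteria, a
Bayesian-bootstrap stochastic-dominance matrix, and a cross-model feature
importance table.

All data are simulated: the package ships a seasonal tag-recapture
generator with configurable truth, so every analysis is fully reproducible
from a seed.

## Worked example

```python
import pandas as pd
from growthstack import run_pipeline

config = {
    "seed": 7,
    "simulate": {"n_fish": 600, "date_range": [2019, 2020]},
    "models": ["baseline_vbgm", "bayesian_vbgm", "xgboost", "lightgbm"],
    "mcmc": {"n_chains": 2, "n_tune": 300, "n_draws": 300},
    "oof_mcmc": {"n_chains": 2, "n_tune": 150, "n_draws": 150},
    "search": {"n_iter": {"xgboost": 5, "lightgbm": 5}},
    "ensembles": {"stack": {"bases": ["bayesian_vbgm", "xgboost"], "folds": 3}},
    "evaluation": {"bootstrap_S": 2000},
    "importance": {"n_repeats": 3},
}
outdir = run_pipeline(config, "runs/demo")
print(pd.read_csv(outdir / "metrics.csv").round(3).to_string(index=False))
```

Output (about a minute on one CPU):

```
           model   RMSE    MAE    R2  AdjR2       AIC     AICC       BIC  pct_rmse_reduction
   bayesian_vbgm  4.854  3.900 0.997  0.996  1159.531 1183.128  1287.249                93.7
    ensemble_bma  4.854  3.900 0.997  0.996  1087.531 1087.759  1100.303                93.7
ensemble_stacked  4.886  3.906 0.997  0.996  1089.889 1090.117  1102.660                93.6
        lightgbm 11.003  8.349 0.982    NaN  7998.160      inf 18573.233                85.6
         xgboost 11.004  8.423 0.982    NaN 12220.197      inf 29535.602                85.6
   baseline_vbgm 76.653 60.534 0.145  0.131  2078.961 2079.098  2088.540                 0.0
```

The covariate-aware Bayesian model recovers the simulation's 5 mm
observation noise almost exactly; the covariate-free baseline curve is far
worse, mirroring the large error reductions this kind of hybrid stack
achieves on real tag-recapture data. The run directory also contains
`dominance.csv` (pairwise P(model a's bootstrap RMSE < model b's)) and
`importance.csv` (per-model and averaged feature importances, min-max
normalized). For this run the top averaged importances are:

```
L1                    0.97
time_at_large         0.73
weight_at_release     0.19
discharge             0.11
release_river_mile    0.10
```

as expected for increment data: release length and time at large dominate.

## Command line

Every stage can also be run from the CLI, writing artifacts plus a
manifest of content digests into the run directory:

```bash
growthstack --config config.yaml --outdir runs/full run-all
# or stage by stage:
growthstack --outdir runs/full simulate
growthstack --outdir runs/full preprocess
growthstack --outdir runs/full fit
growthstack --outdir runs/full ensemble
growthstack --outdir runs/full evaluate
growthstack --outdir runs/full report
```

An empty (or absent) config reproduces the default study conditions:
9,798 simulated fish, a 70/30 split, 4 NUTS chains with 500 warmup +
1,000 posterior draws, the full eleven-model suite, and the printed
hyperparameter search grids. See `growthstack/config.py` for every key.

## Package layout

| Module | Contents |
| --- | --- |
| `growthstack.synthetic` | seasonal covariate series + tag-recapture data generator |
| `growthstack.preprocessing` | interval-weighted covariate integration, split, dual min-max scaling, one-hot indicators |
| `growthstack.curves` | Fabens / Gompertz mean functions, covariate link, least-squares baselines |
| `growthstack.bayes` | growth and linear models, NUTS sampler, posterior prediction |
| `growthstack.ml` | estimator builders, printed search grids, randomized CV tuning |
| `growthstack.ann` | hand-written residual feed-forward network (AdamW, batch norm, warm restarts) |
| `growthstack.ensembles` | out-of-fold stacking, pseudo-BMA weights |
| `growthstack.evaluation` | metrics, pseudo-likelihood AIC/AICc/BIC, Bayesian bootstrap, dominance matrix, R̂/ESS checks |
| `growthstack.importance` | integrated gradients, permutation importance, cross-model aggregation |
| `growthstack.pipeline` / `cli` | staged orchestration with manifests, `growthstack` console script |

See `docs/methods.md` for the statistical methodology and the numerical
choices behind the sampler.
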