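"""Synthetic tag-recapture data with known growth dynamics.

Real tag-recapture growth studies pair individual capture histories (release
and recapture fork lengths, time at large) with reach-level monthly
environmental series (discharge, water temperature, solar insolation, soluble
reactive phosphorus, population biomass).  This module generates datasets with
that structure from a known generative model so the whole analysis pipeline
can be exercised and validated without external data:

* release length L1 follows a truncated log-normal calibrated to configurable
  marginal moments;
* time at large is right-skewed (log-normal, in days);
* monthly covariates follow an annual sinusoid plus noise, bounded to
  configured ranges;
* each record's environmental exposure is the time-weighted average of the
  monthly series over its interval at large (same integration rule the
  preprocessing stage applies to real data);
* the growth coefficient k comes from a log-linear link on min-max-scaled
  covariates plus seasonal indicator effects, and the recapture length is the
  Fabens von Bertalanffy mean plus Gaussian observation noise.

All true parameters are returned alongside the table, so recovery can be
checked exactly.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .curves import fabens_mean, days_to_years

#: environmental / biometric covariates that drive the growth coefficient,
#: in the order their effects are stored.
K_COVARIATES = (
    "release_river_mile",
    "weight_at_release",
    "discharge",
    "water_temperature",
    "solar_insolation",
    "srp_concentration",
    "trout_biomass",
)

ENV_COVARIATES = (
    "discharge",
    "water_temperature",
    "solar_insolation",
    "srp_concentration",
    "trout_biomass",
)

#: target marginal moments (mean, sd, min, max) in native units for each
#: simulated variable; values describe a Colorado River tailwater fishery.
DEFAULT_COVARIATE_MOMENTS: dict[str, tuple[float, float, float, float]] = {
    "release_river_mile": (-3.74, 0.69, -14.89, -1.96),
    "weight_at_release": (118.78, 132.94, 3.50, 1182.00),
    "discharge": (18.65, 4.14, 11.33, 32.11),
    "water_temperature": (16.86, 3.89, 8.65, 27.14),
    "solar_insolation": (50.24, 17.86, 19.18, 105.92),
    "srp_concentration": (0.01, 0.004, 0.0, 0.02),
    "trout_biomass": (12.38, 6.09, 5.56, 34.03),
}

L1_MOMENTS = (187.26, 87.53, 70.0, 457.0)  # mean, sd, min, max (mm)
TIME_AT_LARGE_MOMENTS = (243.47, 285.59, 28.0, 2256.0)  # days

#: month (1-12) at which each seasonal covariate peaks; insolation and
#: temperature peak in summer, discharge in late spring, SRP/biomass broad.
SEASONAL_PEAK_MONTH = {
    "discharge": 6,
    "water_temperature": 8,
    "solar_insolation": 7,
    "srp_concentration": 9,
    "trout_biomass": 10,
}


@dataclass
class MonthlyCovariateSeries:
    """One environmental covariate as a contiguous monthly-mean series."""

    covariate_name: str
    values: dict[tuple[int, int], float]

    def __post_init__(self):
        keys = sorted(self.values)
        if not keys:
            raise ValueError("empty monthly series")
        y, m = keys[0]
        for key in keys:
            if key != (y, m):
                raise ValueError(f"monthly series {self.covariate_name} has a gap at {key}")
            m += 1
            if m == 13:
                y, m = y + 1, 1

    def to_frame(self) -> pd.DataFrame:
        rows = [(y, m, v) for (y, m), v in sorted(self.values.items())]
        return pd.DataFrame(rows, columns=["year", "month", self.covariate_name])


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic tag-recapture study.

    ``true_beta_k`` maps covariate name -> effect on log k (covariates are
    min-max scaled by their configured bounds before entering the link);
    ``true_beta_dummies`` are twelve release-month indicator effects.
    """

    n_fish: int = 9798
    seed: int = 0
    true_Linf: float = 500.0
    true_alpha_k: float = float(np.log(0.5))
    true_beta_k: dict[str, float] = field(
        default_factory=lambda: {"water_temperature": 0.4, "trout_biomass": -0.3}
    )
    true_beta_dummies: tuple[float, ...] = (0.0,) * 12
    sigma_obs: float = 5.0
    covariate_moments: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MOMENTS)
    )
    date_range: tuple[int, int] = (2012, 2021)
    series_noise_scale: float = 1.0

    def __post_init__(self):
        if self.n_fish < 0:
            raise ValueError("n_fish must be non-negative")
        if self.sigma_obs < 0:
            raise ValueError("sigma_obs must be non-negative")
        if self.true_Linf <= 0:
            raise ValueError("true_Linf must be positive")
        if len(self.true_beta_dummies) != 12:
            raise ValueError("true_beta_dummies must have 12 monthly entries")
        unknown = set(self.true_beta_k) - set(K_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates in true_beta_k: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        kwargs = dict(raw)
        if "true_beta_dummies" in kwargs:
            kwargs["true_beta_dummies"] = tuple(kwargs["true_beta_dummies"])
        if "date_range" in kwargs:
            kwargs["date_range"] = tuple(kwargs["date_range"])
        if "covariate_moments" in kwargs:
            kwargs["covariate_moments"] = {
                k: tuple(v) for k, v in kwargs["covariate_moments"].items()
            }
        return cls(**kwargs)

    def truth(self) -> dict:
        """True parameter values as a JSON-serializable dict."""
        d = asdict(self)
        d["true_beta_dummies"] = list(self.true_beta_dummies)
        return d


def _seasonal_template(name: str, mean: float, sd: float, months: np.ndarray) -> np.ndarray:
    """Annual sinusoid with the configured mean and (approximate) sd."""
    peak = SEASONAL_PEAK_MONTH.get(name, 7)
    amplitude = sd * np.sqrt(2.0) * 0.85
    return mean + amplitude * np.cos(2.0 * np.pi * (months - peak) / 12.0)


def generate_monthly_series(config: SimulationConfig) -> list[MonthlyCovariateSeries]:
    """Simulate the monthly environmental series for the study period.

    Each covariate follows a deterministic annual sinusoid (peaking in its
    characteristic month) plus Gaussian noise, clipped to its configured
    [min, max] bounds.  With ``series_noise_scale=0`` the series equals the
    deterministic template exactly (up to bound clipping).
    """
    y0, y1 = config.date_range
    if y1 < y0:
        raise ValueError("empty date range")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    keys = [(y, m) for y in range(y0, y1 + 1) for m in range(1, 13)]
    months = np.array([m for _, m in keys], dtype=float)
    out = []
    for name in ENV_COVARIATES:
        mean, sd, lo, hi = config.covariate_moments[name]
        template = _seasonal_template(name, mean, sd, months)
        noise = rng.normal(0.0, 0.35 * sd * config.series_noise_scale, size=len(keys))
        vals = np.clip(template + noise, lo, hi)
        out.append(MonthlyCovariateSeries(name, dict(zip(keys, vals.tolist()))))
    return out


def _truncated_lognormal_moments(mu, sigma, lo, hi):
    """Mean and sd of a log-normal truncated to [lo, hi] (closed form)."""
    from scipy.stats import norm as _norm

    a, b = (np.log(lo) - mu) / sigma, (np.log(hi) - mu) / sigma
    z = _norm.cdf(b) - _norm.cdf(a)

    def raw(kk):
        return (np.exp(kk * mu + 0.5 * kk**2 * sigma**2)
                * (_norm.cdf(b - kk * sigma) - _norm.cdf(a - kk * sigma)) / z)

    m1 = raw(1)
    var = raw(2) - m1**2
    return m1, np.sqrt(max(var, 1e-12))


def _calibrate_truncated_lognormal(mean, sd, lo, hi):
    """Find (mu, sigma) whose truncated-to-[lo, hi] moments hit the targets."""
    from scipy.optimize import fsolve

    s2 = np.log1p((sd / mean) ** 2)
    x0 = np.array([np.log(mean) - s2 / 2.0, np.sqrt(s2)])

    def eqs(x):
        m, s = _truncated_lognormal_moments(x[0], abs(x[1]), lo, hi)
        return [m - mean, s - sd]

    sol, _, ok, _ = fsolve(eqs, x0, full_output=True)
    if ok != 1:  # fall back to the untruncated calibration
        return float(x0[0]), float(x0[1])
    return float(sol[0]), float(abs(sol[1]))


def _truncated_lognormal(rng, mean, sd, lo, hi, size):
    """Log-normal rejection-bounded to [lo, hi], calibrated so the *truncated*
    distribution has (approximately) the requested mean and sd."""
    mu, sigma = _calibrate_truncated_lognormal(mean, sd, lo, hi)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mu, sigma, size=max(size - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def scale_k_covariates(df: pd.DataFrame, moments: Mapping[str, tuple]) -> np.ndarray:
    """Min-max scale the k-link covariates by their *configured* bounds.

    The generative link operates on this fixed, known scaling (not on
    sample-dependent bounds) so the truth is well-defined for any n.
    """
    cols = []
    for name in K_COVARIATES:
        _, _, lo, hi = moments[name]
        cols.append((df[name].to_numpy(dtype=float) - lo) / (hi - lo))
    return np.column_stack(cols)


def true_growth_rate(df: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Recompute each record's true growth coefficient from the config."""
    Xk = scale_k_covariates(df, config.covariate_moments)
    beta = np.array([config.true_beta_k.get(n, 0.0) for n in K_COVARIATES])
    eta = config.true_alpha_k + Xk @ beta
    eta = eta + np.array(config.true_beta_dummies)[df["release_month"].to_numpy() - 1]
    return np.exp(eta)


def generate_dataset(
    config: SimulationConfig,
    series: list[MonthlyCovariateSeries] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a synthetic tag-recapture table plus its truth sidecar.

    Returns ``(records, truth)`` where ``records`` has one row per capture
    event with columns: L1, L2 (mm), time_at_large (days), release/recapture
    dates, release/recovery month and year, release_river_mile,
    weight_at_release, and the five environmental covariates integrated over
    each record's interval at large.
    """
    # local import: preprocessing reuses nothing from here, avoid cycles
    from .preprocessing import interval_weighted_mean

    if series is None:
        series = generate_monthly_series(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 202]))
    n = config.n_fish
    y0, y1 = config.date_range
    start = dt.date(y0, 1, 1)
    end = dt.date(y1, 12, 31)
    span_days = (end - start).days

    L1 = _truncated_lognormal(rng, *L1_MOMENTS, size=n)
    t_mean, t_sd, t_lo, t_hi = TIME_AT_LARGE_MOMENTS
    t_days = _truncated_lognormal(rng, t_mean, t_sd, t_lo, min(t_hi, span_days - 31), size=n)
    t_days = np.round(t_days)

    # release uniform over the feasible window so recapture stays in coverage
    u = rng.uniform(0.0, 1.0, size=n)
    rel_offset = np.floor(u * (span_days - t_days)).astype(int)
    release_date = np.array([start + dt.timedelta(days=int(d)) for d in rel_offset])
    recapture_date = np.array(
        [d + dt.timedelta(days=int(td)) for d, td in zip(release_date, t_days)]
    )

    mile_mean, mile_sd, mile_lo, mile_hi = config.covariate_moments["release_river_mile"]
    river_mile = np.clip(rng.normal(mile_mean, mile_sd, size=n), mile_lo, mile_hi)
    # weight follows a length-based allometry (W ~ a L^3) with lognormal scatter
    w_mean, w_sd, w_lo, w_hi = config.covariate_moments["weight_at_release"]
    w_pred = w_mean * (L1 / L1_MOMENTS[0]) ** 3
    weight = np.clip(w_pred * rng.lognormal(0.0, 0.25, size=n), w_lo, w_hi)

    df = pd.DataFrame(
        {
            "fish_id": np.arange(n),
            "L1": L1,
            "time_at_large": t_days,
            "release_date": release_date,
            "recapture_date": recapture_date,
            "release_river_mile": river_mile,
            "weight_at_release": weight,
        }
    )
    df["release_month"] = [d.month for d in release_date]
    df["release_year"] = [d.year for d in release_date]
    df["recovery_month"] = [d.month for d in recapture_date]
    df["recovery_year"] = [d.year for d in recapture_date]

    by_name = {s.covariate_name: s for s in series}
    for name in ENV_COVARIATES:
        s = by_name[name]
        df[name] = [
            interval_weighted_mean(rd, cd, s)
            for rd, cd in zip(df["release_date"], df["recapture_date"])
        ]

    k = true_growth_rate(df, config)
    mean_L2 = fabens_mean(L1, config.true_Linf, k, days_to_years(t_days))
    df["L2"] = mean_L2 + rng.normal(0.0, config.sigma_obs, size=n)
    df["true_k"] = k

    truth = config.truth()
    return df, truth


def write_dataset(df: pd.DataFrame, truth: dict, csv_path, truth_path=None) -> None:
    """Write records as CSV and the generative truth as a JSON sidecar."""
    csv_path = Path(csv_path)
    df.to_csv(csv_path, index=False)
    if truth_path is None:
        truth_path = csv_path.with_suffix(".truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)


def read_dataset(csv_path) -> pd.DataFrame:
    df = pd.read_csv(csv_path, parse_dates=["release_date", "recapture_date"])
    for col in ("release_date", "recapture_date"):
        df[col] = df[col].dt.date
    return df
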