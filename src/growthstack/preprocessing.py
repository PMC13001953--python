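"""Record preprocessing: covariate integration, splitting, scaling, encoding.

Raw tag-recapture records carry release/recapture dates and lengths; the
environmental context lives in separate monthly series.  This module aligns
the two by interval-weighted averaging over each record's time at large, then
produces train/test design matrices under two scaling strategies:

* ``full``    — every continuous predictor min-max scaled to [0, 1]
                (used by the machine-learning models);
* ``partial`` — identical, except release length (L1) and time at large keep
                their native units (mm, days) for the mechanistic models.

Scaling parameters are always learned from the training rows only and the
response (L2, mm) is never scaled.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: continuous predictors, in design-matrix order
CONTINUOUS_FEATURES = (
    "L1",
    "time_at_large",
    "release_river_mile",
    "weight_at_release",
    "discharge",
    "water_temperature",
    "solar_insolation",
    "srp_concentration",
    "trout_biomass",
)

#: predictors kept in native units under the partial strategy
PARTIAL_SCALING_EXCLUDED = ("L1", "time_at_large")

INDICATOR_FACTORS = ("release_month", "recovery_month", "release_year", "recovery_year")


class CoverageError(ValueError):
    """A record's interval at large falls outside the monthly series coverage."""


def _month_span(year: int, month: int) -> tuple[dt.date, dt.date]:
    first = dt.date(year, month, 1)
    nxt = dt.date(year + 1, 1, 1) if month == 12 else dt.date(year, month + 1, 1)
    return first, nxt


def interval_weighted_mean(start: dt.date, end: dt.date, series) -> float:
    """Time-weighted average of a monthly series over [start, end).

    If the interval lies within one calendar month, that month's mean is
    assigned directly; otherwise each overlapped month contributes its mean
    weighted by the number of interval days falling in it.
    """
    if end < start:
        raise ValueError("interval end precedes start")
    values = series.values
    if (start.year, start.month) == (end.year, end.month) or end == start:
        key = (start.year, start.month)
        if key not in values:
            raise CoverageError(f"{series.covariate_name}: no coverage for {key}")
        return float(values[key])

    total_days = (end - start).days
    acc = 0.0
    y, m = start.year, start.month
    while (y, m) <= (end.year, end.month):
        first, nxt = _month_span(y, m)
        overlap = (min(end, nxt) - max(start, first)).days
        if overlap > 0:
            key = (y, m)
            if key not in values:
                raise CoverageError(f"{series.covariate_name}: no coverage for {key}")
            acc += overlap * values[key]
        y, m = (y + 1, 1) if m == 12 else (y, m + 1)
    return acc / total_days


def integrate_covariates(records: pd.DataFrame, series_list) -> pd.DataFrame:
    """Fill each record's environmental columns from the monthly series."""
    out = records.copy()
    for series in series_list:
        out[series.covariate_name] = [
            interval_weighted_mean(rd, cd, series)
            for rd, cd in zip(out["release_date"], out["recapture_date"])
        ]
    return out


def split_train_test(records: pd.DataFrame, ratio: float = 0.7, seed: int = 0):
    """Random disjoint train/test partition with floor(ratio * n) training rows."""
    n = len(records)
    if n == 0:
        raise ValueError("cannot split an empty table")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(ratio * n))
    train = records.iloc[perm[:n_train]].copy()
    test = records.iloc[perm[n_train:]].copy()
    return train, test


@dataclass
class ScalerParams:
    """Per-feature (min, max) learned from training rows only."""

    mins: dict[str, float]
    maxs: dict[str, float]
    excluded: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"mins": self.mins, "maxs": self.maxs, "excluded": list(self.excluded)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(mins=dict(d["mins"]), maxs=dict(d["maxs"]), excluded=tuple(d["excluded"]))


def fit_scaler(train: pd.DataFrame, strategy: str = "full",
               features=CONTINUOUS_FEATURES, bounds=None) -> ScalerParams:
    """Learn min-max parameters on the training split.

    ``strategy='partial'`` marks L1 and time_at_large as excluded so they pass
    through in native units.  A constant training feature is flagged (it will
    map to 0 everywhere under the convention (x - min) / 1).  ``bounds`` maps
    feature name -> (min, max) to pin specific features to known ranges (e.g.
    the generative bounds of a simulation, so fitted coefficients live in the
    same parameterization as the simulation truth).
    """
    if len(train) == 0:
        raise ValueError("cannot fit scaler on empty training data")
    if strategy not in ("full", "partial"):
        raise ValueError(f"unknown scaling strategy {strategy!r}")
    excluded = PARTIAL_SCALING_EXCLUDED if strategy == "partial" else ()
    bounds = bounds or {}
    mins, maxs = {}, {}
    for f in features:
        if f in bounds:
            mins[f], maxs[f] = float(bounds[f][0]), float(bounds[f][1])
            continue
        col = train[f].to_numpy(dtype=float)
        mins[f] = float(col.min())
        maxs[f] = float(col.max())
        if maxs[f] == mins[f] and f not in excluded:
            logger.warning("feature %s is constant in training data; it scales to 0", f)
    return ScalerParams(mins=mins, maxs=maxs, excluded=tuple(excluded))


def apply_scaler(data: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    """Min-max transform the included features; excluded columns untouched."""
    out = data.copy()
    for f in params.mins:
        if f not in out.columns:
            raise KeyError(f"feature {f!r} missing from data")
        if f in params.excluded:
            continue
        lo, hi = params.mins[f], params.maxs[f]
        denom = (hi - lo) if hi > lo else 1.0
        out[f] = (out[f].astype(float) - lo) / denom
    return out


def inverse_scaler(data: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    out = data.copy()
    for f in params.mins:
        if f in params.excluded or f not in out.columns:
            continue
        lo, hi = params.mins[f], params.maxs[f]
        denom = (hi - lo) if hi > lo else 1.0
        out[f] = out[f].astype(float) * denom + lo
    return out


def encode_indicators(records: pd.DataFrame, levels: dict[str, list] | None = None):
    """One 0/1 column per observed level of the four seasonal/annual factors.

    Full one-hot (no reference level dropped).  ``levels`` fixes the level
    sets (e.g. from the training split) so train and test encode identically;
    by default the observed levels of ``records`` are used.
    """
    ok = records["release_month"].isin(range(1, 13)) & records["recovery_month"].isin(range(1, 13))
    if not ok.all():
        raise ValueError("month outside 1-12 in indicator factors")
    if levels is None:
        levels = {f: sorted(records[f].unique().tolist()) for f in INDICATOR_FACTORS}
    cols = {}
    for f in INDICATOR_FACTORS:
        vals = records[f].to_numpy()
        for lv in levels[f]:
            cols[f"{f}_{lv}"] = (vals == lv).astype(float)
    Xd = pd.DataFrame(cols, index=records.index)
    return Xd, levels


@dataclass
class DesignMatrices:
    """Scaled continuous matrix, indicator matrix and unscaled response."""

    Xc: pd.DataFrame
    Xd: pd.DataFrame
    y: pd.Series
    ids: pd.Index = field(default=None)

    def __post_init__(self):
        if self.ids is None:
            self.ids = self.Xc.index
        if not (len(self.Xc) == len(self.Xd) == len(self.y)):
            raise ValueError("design matrix row counts disagree")

    @property
    def X(self) -> np.ndarray:
        """Continuous + indicator features as one numeric matrix."""
        return np.column_stack([self.Xc.to_numpy(float), self.Xd.to_numpy(float)])

    def take(self, positions) -> "DesignMatrices":
        """Row subset by integer position (used for cross-validation folds)."""
        positions = np.asarray(positions)
        return DesignMatrices(
            Xc=self.Xc.iloc[positions],
            Xd=self.Xd.iloc[positions],
            y=self.y.iloc[positions],
            ids=self.ids[positions],
        )

    @property
    def feature_names(self) -> list[str]:
        return list(self.Xc.columns) + list(self.Xd.columns)


def build_design_matrices(
    train: pd.DataFrame,
    test: pd.DataFrame,
    strategy: str = "full",
    features=CONTINUOUS_FEATURES,
    bounds=None,
) -> tuple[DesignMatrices, DesignMatrices, ScalerParams]:
    """Fit the scaler on train, apply to both splits, encode indicators."""
    params = fit_scaler(train, strategy=strategy, features=features, bounds=bounds)
    levels = None
    out = []
    for df in (train, test):
        scaled = apply_scaler(df, params)
        Xd, levels = encode_indicators(df, levels)
        Xc = scaled[list(features)]
        out.append(DesignMatrices(Xc=Xc, Xd=Xd, y=df["L2"].astype(float), ids=df.index))
    return out[0], out[1], params
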