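"""Mechanistic growth curves for tag-recapture data.

The Fabens re-parameterization of the von Bertalanffy growth model predicts
length at recapture (L2) from length at release (L1) and time at large (t),
so no age information is needed::

    L2 = L1 + (Linf - L1) * (1 - exp(-k * t))

The Gompertz curve is the sigmoid alternative::

    L2 = Linf * exp(-exp(-k * t))

Both share the asymptote ``Linf`` (mm) and a growth coefficient ``k``
(per year).  In the covariate-dependent Bayesian models, ``k`` is
observation-specific through a log-linear link, which keeps it positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

DAYS_PER_YEAR = 365.25


def days_to_years(days):
    """Convert time at large from days (as recorded) to years (as modelled)."""
    return np.asarray(days, dtype=float) / DAYS_PER_YEAR


def fabens_mean(L1, Linf, k, t):
    """Expected recapture length under the Fabens von Bertalanffy model.

    Parameters
    ----------
    L1 : array_like
        Fork length at release (mm).
    Linf : float or array_like
        Asymptotic length (mm), > 0.
    k : float or array_like
        Growth coefficient (per year), >= 0.
    t : array_like
        Time at large in *years*, >= 0.
    """
    L1 = np.asarray(L1, dtype=float)
    decay = np.exp(-np.asarray(k, dtype=float) * np.asarray(t, dtype=float))
    return Linf - (Linf - L1) * decay


def gompertz_mean(Linf, k, t):
    """Expected recapture length under the Gompertz model (no L1 anchor)."""
    return Linf * np.exp(-np.exp(-np.asarray(k, dtype=float) * np.asarray(t, dtype=float)))


def growth_rate_link(alpha_k, Xc_row, beta_k, Xd_row=None, beta_dummies=None):
    """Log-linear link for the growth coefficient: k = exp(a + Xc·b + Xd·bd).

    Accepts single rows or matrices; always returns strictly positive values.
    """
    eta = np.asarray(alpha_k, dtype=float) + np.asarray(Xc_row, dtype=float) @ np.asarray(beta_k, dtype=float)
    if Xd_row is not None and beta_dummies is not None and np.size(beta_dummies):
        eta = eta + np.asarray(Xd_row, dtype=float) @ np.asarray(beta_dummies, dtype=float)
    return np.exp(eta)


@dataclass
class BaselineFit:
    """Least-squares fit of a no-covariate growth curve in t only."""

    model: str
    Linf: float
    K: float
    fitted: np.ndarray
    rss: float

    def predict(self, t_years) -> np.ndarray:
        t = np.asarray(t_years, dtype=float)
        if self.model == "vbgm":
            return self.Linf * (1.0 - np.exp(-self.K * t))
        return self.Linf * np.exp(-np.exp(-self.K * t))


def fit_baseline(model: str, t_years, L2, p0=(500.0, 0.5), maxfev=20000) -> BaselineFit:
    """Fit a covariate-free benchmark growth curve by nonlinear least squares.

    These benchmarks regress recapture length on elapsed time alone: for the
    von Bertalanffy form ``L2 = Linf (1 - exp(-K t))`` and the Gompertz form
    ``L2 = Linf exp(-exp(-K t))``.  Because neither uses the release length,
    they carry very little signal in tag-recapture data and serve purely as
    the comparison floor for percent-error-reduction reporting.
    """
    if model not in ("vbgm", "gompertz"):
        raise ValueError(f"unknown baseline model {model!r}")
    t = np.asarray(t_years, dtype=float)
    y = np.asarray(L2, dtype=float)
    if t.size == 0:
        raise ValueError("cannot fit baseline on empty data")

    if model == "vbgm":
        def f(tt, Linf, K):
            return Linf * (1.0 - np.exp(-K * tt))
    else:
        def f(tt, Linf, K):
            return Linf * np.exp(-np.exp(-K * tt))

    try:
        popt, _ = curve_fit(f, t, y, p0=np.asarray(p0, dtype=float), maxfev=maxfev)
    except RuntimeError as exc:  # pragma: no cover - optimizer pathologies
        raise RuntimeError(f"baseline {model} fit did not converge: {exc}") from exc
    fitted = f(t, *popt)
    rss = float(np.sum((y - fitted) ** 2))
    return BaselineFit(model=model, Linf=float(popt[0]), K=float(popt[1]), fitted=fitted, rss=rss)
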