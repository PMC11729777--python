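"""Trend model fitting and out-of-sample evaluation of the monthly series.

The series of monthly match counts is split chronologically into a 2:1
train/test partition, an ordinary-least-squares line ``count = m*t + b``
is fitted on the training prefix (t is the 0-based month index of the
*full* series, so the intercept stays interpretable across splits), and
the fit is scored on the held-out suffix with RMSE and out-of-sample R²:

    R² = 1 - SS_res / SS_tot,   SS_tot about the *test-set* mean.

Out-of-sample R² can be negative -- a trend model extrapolated into a
regime it never saw can do worse than predicting the test mean.

``forecast_adapter`` gives external forecasters a uniform plug-in
contract; the built-ins are the internal OLS extrapolation and a
seasonal-naive baseline (same calendar month, previous year).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError, SingularFitError

__all__ = ["SeriesSplit", "LinearFit", "FitMetrics", "split_series",
           "fit_ols", "evaluate", "predict", "forecast_adapter",
           "register_adapter", "adapter_names"]


@dataclass(frozen=True)
class SeriesSplit:
    train: pd.DataFrame
    test: pd.DataFrame
    ratio: float


@dataclass(frozen=True)
class LinearFit:
    m: float          # slope: matches/month per month index
    b: float          # intercept: matches/month at t = 0
    stderr_m: float   # standard error of the slope


@dataclass(frozen=True)
class FitMetrics:
    rmse: float
    r2: float          # NaN when the test series has zero variance
    r2_defined: bool = True


def split_series(series: pd.DataFrame, ratio: float = 2 / 3) -> SeriesSplit:
    """Chronological prefix/suffix split; |train| = round(ratio * n)."""
    if not (0.0 < ratio < 1.0):
        raise ConfigurationError(f"split ratio {ratio} outside (0, 1)")
    n = len(series)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 months to split, got {n}")
    k = int(round(ratio * n))
    k = min(max(k, 1), n - 1)
    return SeriesSplit(train=series.iloc[:k].reset_index(drop=True),
                       test=series.iloc[k:].reset_index(drop=True),
                       ratio=ratio)


def fit_ols(train: pd.DataFrame) -> LinearFit:
    """Closed-form least squares of count on month index."""
    t = train["t"].to_numpy(dtype=float)
    y = train["count"].to_numpy(dtype=float)
    if len(t) < 2 or np.unique(t).size < 2:
        raise SingularFitError("need >= 2 distinct time indices")
    res = stats.linregress(t, y)
    return LinearFit(m=float(res.slope), b=float(res.intercept),
                     stderr_m=float(res.stderr))


def predict(fit: LinearFit, t: np.ndarray) -> np.ndarray:
    return fit.m * np.asarray(t, dtype=float) + fit.b


def evaluate(fit: LinearFit, test: pd.DataFrame) -> FitMetrics:
    """RMSE and out-of-sample R² of a fit on the held-out months."""
    if len(test) == 0:
        raise InsufficientDataError("empty test series")
    y = test["count"].to_numpy(dtype=float)
    yhat = predict(fit, test["t"].to_numpy(dtype=float))
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return FitMetrics(rmse=rmse, r2=math.nan, r2_defined=False)
    ss_res = float(np.sum((y - yhat) ** 2))
    return FitMetrics(rmse=rmse, r2=1.0 - ss_res / ss_tot)


# --------------------------------------------------------------------------
# Forecast adapters

Adapter = Callable[[pd.DataFrame, int], np.ndarray]
_ADAPTERS: dict[str, Adapter] = {}


def register_adapter(name: str, fn: Adapter) -> None:
    _ADAPTERS[name] = fn


def adapter_names() -> list[str]:
    return sorted(_ADAPTERS)


def forecast_adapter(name: str, train: pd.DataFrame,
                     horizon: int) -> np.ndarray:
    """Predict the ``horizon`` months following the training prefix with
    the named adapter."""
    if name not in _ADAPTERS:
        raise KeyError(f"unknown forecast adapter {name!r}; "
                       f"registered: {adapter_names()}")
    if horizon < 1:
        raise ConfigurationError("horizon must be >= 1")
    return _ADAPTERS[name](train, horizon)


def _ols_adapter(train: pd.DataFrame, horizon: int) -> np.ndarray:
    fit = fit_ols(train)
    t_last = int(train["t"].iloc[-1])
    return predict(fit, np.arange(t_last + 1, t_last + 1 + horizon))


def _seasonal_naive_adapter(train: pd.DataFrame, horizon: int,
                            period: int = 12) -> np.ndarray:
    """Forecast each month with the most recent observation from the same
    phase of the seasonal cycle; falls back to the last value when the
    training series is shorter than one period."""
    y = train["count"].to_numpy(dtype=float)
    n = len(y)
    out = np.empty(horizon)
    for h in range(horizon):
        idx = n + h - period
        while idx >= n:  # horizon beyond one period: recurse into forecasts
            idx -= period
        out[h] = y[idx] if idx >= 0 else y[-1]
    return out


register_adapter("ols", _ols_adapter)
register_adapter("seasonal_naive", _seasonal_naive_adapter)
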