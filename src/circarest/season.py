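"""Seasonal coupling between T_night and night length.

Weekly averages of T_night (Mon-Thu for typical weekdays, Fri-Sun for
weekends) are regressed linearly on the matching averages of N_length,
T_night_bar = beta * N_length_bar + alpha.  The regression-implied seasonal
swing is

    delta_season = beta * [N_length(d=356) - N_length(d=172)]

(winter minus summer solstice).  Phase alignment between the daily series
is quantified with the normalised lagged cross-correlation

    rho(tau) = 1/(n - |tau|) * sum_i z(X_i) * z(Y_{i+tau})

summed over the overlapping index range, where z() standardises with the
*global* mean and population SD of each series.  Inputs are z-scored before
the computation (the formula re-standardises, which is idempotent); missing
days are handled by pairwise deletion with the day index kept intact, the
denominator then being the number of contributing pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .solar import NightLengthSeries

__all__ = [
    "RegressionResult",
    "CrossCorrelation",
    "regress",
    "delta_season",
    "cross_correlation",
    "pearson_by_city",
]


@dataclass
class RegressionResult:
    beta: float  # hours of T_night per hour of night length
    alpha: float  # hours
    r: float
    p: float
    n: int


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def regress(series_t, series_n) -> RegressionResult:
    """OLS of T_night_bar on N_length_bar; r and p from the same pairs."""
    t, n = _paired(series_t, series_n)
    if t.size < 3:
        raise ValueError(f"need at least 3 paired points, got {t.size}")
    if np.ptp(n) == 0:
        raise ValueError("regressor is constant; slope undefined")
    res = stats.linregress(n, t)
    return RegressionResult(
        beta=float(res.slope),
        alpha=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=int(t.size),
    )


def delta_season(beta: float, nights: NightLengthSeries) -> float:
    """beta * [N_length(356) - N_length(172)], hours."""
    return float(beta * (nights.value(356) - nights.value(172)))


@dataclass
class CrossCorrelation:
    lags: np.ndarray
    rho: np.ndarray
    best_lag: int


def _zscore(x: np.ndarray) -> np.ndarray:
    mean = np.nanmean(x)
    sd = np.nanstd(x, ddof=0)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("zero-variance input")
    return (x - mean) / sd


def cross_correlation(x, y, tau_max: int) -> CrossCorrelation:
    """Normalised cross-correlation over integer lags in [-tau_max, tau_max].

    Positive lag pairs X_i with Y_{i+tau} (Y lagging X by tau days gives a
    positive best lag).  The best lag maximises rho, ties broken toward 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = x.size
    if tau_max > n // 2:
        raise ValueError("tau_max must not exceed n/2")
    zx = _zscore(x)
    zy = _zscore(y)
    lags = np.arange(-tau_max, tau_max + 1)
    rho = np.empty(lags.size)
    for j, tau in enumerate(lags):
        if tau >= 0:
            a, b = zx[: n - tau], zy[tau:]
        else:
            a, b = zx[-tau:], zy[: n + tau]
        prod = a * b
        m = np.isfinite(prod)
        rho[j] = prod[m].sum() / m.sum() if m.any() else np.nan
    best = np.nanmax(rho)
    candidates = lags[np.isclose(rho, best, rtol=0.0, atol=1e-12)]
    best_lag = int(candidates[np.lexsort((candidates > 0, np.abs(candidates)))[0]])
    return CrossCorrelation(lags=lags, rho=rho, best_lag=best_lag)


def pearson_by_city(t_night_series, n_length_series) -> tuple[float, float]:
    """Pearson r with two-sided p between daily T_night and N_length."""
    t, n = _paired(t_night_series, n_length_series)
    if t.size < 3:
        raise ValueError(f"need at least 3 paired points, got {t.size}")
    r, p = stats.pearsonr(t, n)
    return float(r), float(p)
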