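"""Synthetic call-record generator with a known resting-dynamics truth channel.

The original population-scale call records are proprietary, so every
downstream stage is exercised on synthetic data whose ground truth is known
by construction.  The generative model, per city:

* **Temperatures**: theta(d) = mean + amplitude * cos(2 pi (d-202)/365) +
  N(0, noise_sd^2), peaking in late July.

* **Truth channels**: the nocturnal and afternoon resting durations are set
  to

      T_night_true(d) = a + b * N_length(d) - c * max(0, theta(d) - theta*)
      T_break_true(d) = e + c' * max(0, theta(d) - theta*)

  i.e. the night rest tracks night length with slope ``b`` and is eroded on
  hot days, while the afternoon break grows above the threshold theta*.
  When c' = c (the default, "conserved" mode) the total daily rest
  T_night + T_break has zero temperature response.

* **Calls**: user activity is bursty — on any day a user is active with
  probability rate/burst_mean and an active user places 1 + Poisson(burst_mean - 1)
  calls, keeping the long-run mean at ``rate`` calls per user-day (~330
  calls/user/year at the default 0.9).  Call times are i.i.d. draws from a
  two-Gaussian daily mixture on the extended [4, 28) axis: a *constant*
  morning/noon mode (mornings are anchored by work schedules) and an
  evening mode whose centre and width vary by day.

The evening mode is positioned by inverting the statistics the extraction
pipeline actually measures.  The pipeline's P_F / P_L are the per-user
first-morning / last-night calls, i.e. window-restricted minimum / maximum
order statistics of the mixture; their distributions have closed-form CDFs
through the probability generating function of the per-user call count.
For each day the generator solves (Brent root-finding on sigma_N) so that

    (t_N - sigma_N) - (t_M + sigma_M)                    = T_break_true(d)
    24 - (mean+sd of last-call dist) + (mean-sd of first-call dist)
                                                          = T_night_true(d)

hold exactly at the distribution level.  Because the morning side is
day-constant, the pairing of day d's night with day d+1's morning needs no
chain coupling.  What remains between truth and pipeline estimate is
sampling noise, binning and smoothing (a few minutes at the default 2000
users).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .preprocess import WINDOWS
from .profiles import weekday_labels
from .solar import CityConfig, NightLengthSeries

__all__ = [
    "GenParams",
    "SynthUser",
    "TemperatureSeries",
    "GroundTruth",
    "generate_temperatures",
    "generate_users",
    "generate_calls",
]

DAY_LO, DAY_HI = WINDOWS["full"]


@dataclass(frozen=True)
class GenParams:
    """Generative parameters; defaults define the reference study conditions."""

    # truth-channel coefficients
    a_night: float = 5.5  # h: T_night intercept
    b_night: float = 0.4  # h of night rest per h of night length
    c_night: float = 0.05  # h/degC erosion of night rest above theta*
    c_break: float = 0.05  # h/degC growth of afternoon break above theta*
    theta_star: float = 22.0  # degC threshold
    e_break: float = 4.2  # h: afternoon break baseline
    # mixture geometry
    t_morning: float = 12.0  # constant noon-mode centre, h
    sigma_morning: float = 1.5  # constant noon-mode width, h
    t_evening: float = 20.0  # evening-mode nominal centre (solver initialisation)
    w_morning: float = 0.55  # noon-mode weight
    # calling intensity
    rate: float = 0.9  # mean calls per user-day (~330/yr)
    burst_mean: float = 4.5  # mean calls per *active* user-day
    # optional weekend effect: Fri/Sat nights shortened by this much (h)
    weekend_night_delay: float = 0.0

    @property
    def conserved(self) -> bool:
        return self.c_night == self.c_break

    @property
    def p_active(self) -> float:
        return self.rate / self.burst_mean


@dataclass(frozen=True)
class SynthUser:
    user_id: str
    age: int
    gender: str
    postal_lat: float
    postal_lon: float
    mact_lat: float
    mact_lon: float
    violation: str  # "valid", "far_both", "split", "age"


@dataclass
class TemperatureSeries:
    """Daily maximum temperature theta(d), degC, for one city-year."""

    city: CityConfig
    year: int
    values: np.ndarray  # shape (365,)

    def value(self, d: int) -> float:
        return float(self.values[d - 1])


@dataclass
class GroundTruth:
    """Truth channel for parameter-recovery tests."""

    city: str
    year: int
    t_night_true: np.ndarray  # (365,), NaN where undefined (d = 365)
    t_break_true: np.ndarray  # (365,)
    t_evening: np.ndarray  # solved evening-mode centres
    sigma_evening: np.ndarray  # solved evening-mode widths
    params: GenParams
    valid_user_ids: list = field(default_factory=list)
    violations: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "city": self.city,
            "year": self.year,
            "params": asdict(self.params),
            "t_night_true": [None if np.isnan(v) else round(float(v), 6) for v in self.t_night_true],
            "t_break_true": [round(float(v), 6) for v in self.t_break_true],
            "t_evening": [round(float(v), 6) for v in self.t_evening],
            "sigma_evening": [round(float(v), 6) for v in self.sigma_evening],
            "valid_user_ids": list(self.valid_user_ids),
            "violations": dict(self.violations),
        }


def generate_temperatures(
    city: CityConfig,
    year: int,
    mean: float = 20.0,
    amplitude: float = 6.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> TemperatureSeries:
    """Seasonal daily-maximum temperature with Gaussian day-to-day noise."""
    if amplitude < 0 or noise_sd < 0:
        raise ValueError("amplitude and noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    d = np.arange(1, 366)
    values = mean + amplitude * np.cos(2 * np.pi * (d - 202) / 365.0)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=365)
    return TemperatureSeries(city=city, year=year, values=values)


# --- synthetic demographics -------------------------------------------------

_KM_PER_DEG_LAT = 111.19


def _offset_latlon(lat0, lon0, dist_km, bearing_rad):
    dlat = dist_km * np.cos(bearing_rad) / _KM_PER_DEG_LAT
    dlon = dist_km * np.sin(bearing_rad) / (_KM_PER_DEG_LAT * np.cos(np.deg2rad(lat0)))
    return lat0 + dlat, lon0 + dlon


def generate_users(
    city: CityConfig, n_users: int, frac_invalid: float = 0.0, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic users with planted filter violations.

    A fraction ``1 - frac_invalid`` satisfies all residency and age rules
    (both locations inside a 10 km disc around the centre, age 30-75); the
    rest violate exactly one rule, cycling over the three types: both
    locations far from the centre (``far_both``), MACT near the centre but
    postal >= 30 km away (``split``), and age outside [30, 75] (``age``).
    Returns the users frame and a user_id-indexed Series of violation tags
    (the truth channel for filter tests).
    """
    if not 0.0 <= frac_invalid <= 1.0:
        raise ValueError("frac_invalid must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_invalid = int(round(n_users * frac_invalid))
    tags = ["valid"] * (n_users - n_invalid)
    kinds = ["far_both", "split", "age"]
    tags += [kinds[i % 3] for i in range(n_invalid)]
    rng.shuffle(tags)

    rows = []
    for i, tag in enumerate(tags):
        age = int(rng.integers(30, 76))
        # disc sampling: sqrt for uniform areal density
        r1, r2 = 10.0 * np.sqrt(rng.random(2))
        b1, b2 = 2 * np.pi * rng.random(2)
        mact = _offset_latlon(city.latitude, city.longitude, r1, b1)
        postal = _offset_latlon(city.latitude, city.longitude, r2, b2)
        if tag == "far_both":
            base = _offset_latlon(
                city.latitude, city.longitude, 40.0 + 20.0 * rng.random(), 2 * np.pi * rng.random()
            )
            mact = _offset_latlon(base[0], base[1], 3.0 * rng.random(), 2 * np.pi * rng.random())
            postal = _offset_latlon(base[0], base[1], 3.0 * rng.random(), 2 * np.pi * rng.random())
        elif tag == "split":
            mact = _offset_latlon(city.latitude, city.longitude, 5.0 * np.sqrt(rng.random()), 2 * np.pi * rng.random())
            postal = _offset_latlon(mact[0], mact[1], 35.0 + 20.0 * rng.random(), 2 * np.pi * rng.random())
        elif tag == "age":
            age = int(rng.choice(np.concatenate([np.arange(18, 30), np.arange(76, 91)])))
        rows.append(
            {
                "user_id": f"u{i:06d}",
                "age": age,
                "gender": str(rng.choice(["f", "m"])),
                "postal_lat": postal[0],
                "postal_lon": postal[1],
                "mact_lat": mact[0],
                "mact_lon": mact[1],
            }
        )
    users = pd.DataFrame(
        rows,
        columns=["user_id", "age", "gender", "postal_lat", "postal_lon", "mact_lat", "mact_lon"],
    )
    truth = pd.Series(tags, index=users["user_id"], name="violation")
    return users, truth


# --- order-statistic envelope machinery -------------------------------------

_GRID_STEP = 0.005  # hours; ~0.3 min quadrature resolution


def _mixture_cdf(x, t_m, s_m, t_n, s_n, w_m):
    return w_m * norm.cdf(x, t_m, s_m) + (1 - w_m) * norm.cdf(x, t_n, s_n)


def _count_pgf(s: np.ndarray, burst_extra: float) -> np.ndarray:
    # calls per active user-day: k = 1 + Poisson(burst_extra)
    return s * np.exp(burst_extra * (s - 1.0))


def _extreme_stats(
    t_m, s_m, t_n, s_n, w_m, burst_extra, window: str, which: str
) -> tuple[float, float]:
    """Mean and SD of the per-user window min ('first') or max ('last') call time.

    Closed-form CDF: with per-call window probability q and within-window
    CDF G, the number of window calls of an active user has PGF
    Pk(s) = s exp(burst_extra (s-1)); conditioned on at least one,

        P(min > x) = (Pk(1 - q G(x)) - Pk(1 - q)) / (1 - Pk(1 - q))
        P(max <= x) = (Pk(1 - q (1 - G(x))) - Pk(1 - q)) / (1 - Pk(1 - q))
    """
    lo, hi = WINDOWS[window]
    total = _mixture_cdf(DAY_HI, t_m, s_m, t_n, s_n, w_m) - _mixture_cdf(
        DAY_LO, t_m, s_m, t_n, s_n, w_m
    )
    c_lo = _mixture_cdf(lo, t_m, s_m, t_n, s_n, w_m)
    c_hi = _mixture_cdf(hi, t_m, s_m, t_n, s_n, w_m)
    q = (c_hi - c_lo) / total
    x = np.arange(lo, hi + _GRID_STEP / 2, _GRID_STEP)
    G = (_mixture_cdf(x, t_m, s_m, t_n, s_n, w_m) - c_lo) / (c_hi - c_lo)
    G = np.clip(G, 0.0, 1.0)
    p_none = float(_count_pgf(np.array([1.0 - q]), burst_extra)[0])
    denom = 1.0 - p_none
    if which == "first":
        cdf = 1.0 - (_count_pgf(1.0 - q * G, burst_extra) - p_none) / denom
    elif which == "last":
        cdf = (_count_pgf(1.0 - q * (1.0 - G), burst_extra) - p_none) / denom
    else:
        raise ValueError(which)
    cdf = np.clip(cdf, 0.0, 1.0)
    pdf = np.gradient(cdf, x)
    mass = np.trapezoid(pdf, x)
    mean = np.trapezoid(x * pdf, x) / mass
    var = np.trapezoid((x - mean) ** 2 * pdf, x) / mass
    return float(mean), float(np.sqrt(max(var, 0.0)))


def _solve_evening_mode(
    g_night: float, g_break: float, params: GenParams
) -> tuple[float, float]:
    """Solve (t_N, sigma_N) so the pipeline's envelopes hit both truths.

    The afternoon-break identity pins t_N = sigma_N + C with
    C = T_break + t_M + sigma_M; the night identity is then a monotone
    scalar equation in sigma_N, solved by Brent's method.
    """
    t_m, s_m, w_m = params.t_morning, params.sigma_morning, params.w_morning
    burst_extra = params.burst_mean - 1.0
    C = g_break + t_m + s_m

    def residual(s_n: float) -> float:
        t_n = s_n + C
        m_f, s_f = _extreme_stats(t_m, s_m, t_n, s_n, w_m, burst_extra, "morning", "first")
        m_l, s_l = _extreme_stats(t_m, s_m, t_n, s_n, w_m, burst_extra, "night", "last")
        realized = 24.0 - (m_l + s_l) + (m_f - s_f)
        return realized - g_night

    lo_bracket, hi_bracket = 0.3, 5.5
    s_n = brentq(residual, lo_bracket, hi_bracket, xtol=1e-6)
    return s_n + C, s_n


# --- call generation ---------------------------------------------------------


def _truth_channels(
    nights: NightLengthSeries, temps: TemperatureSeries, params: GenParams, year: int
) -> tuple[np.ndarray, np.ndarray]:
    relu = np.maximum(0.0, temps.values - params.theta_star)
    t_night = params.a_night + params.b_night * nights.values - params.c_night * relu
    t_break = params.e_break + params.c_break * relu
    if params.weekend_night_delay:
        wd = weekday_labels(year)
        fri_sat = (wd == 4) | (wd == 5)
        t_night = t_night - params.weekend_night_delay * fri_sat
    return t_night, t_break


def generate_calls(
    city: CityConfig,
    users: pd.DataFrame,
    year: int,
    nights: NightLengthSeries,
    temps: TemperatureSeries,
    params: GenParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one year of outgoing-call records plus the ground truth.

    Returns a time-sorted frame (user_id, timestamp with the city's fixed
    UTC offset) and the :class:`GroundTruth`.  Identical seeds give
    identical output.  T_night_true(365) is NaN — its measurement would
    need the next year's first morning.
    """
    params = params or GenParams()
    rng = np.random.default_rng(seed)
    t_night_true, t_break_true = _truth_channels(nights, temps, params, year)

    # solve the evening mode day by day (warm-started bracket not needed;
    # Brent on [0.3, 5.5] is cheap)
    t_even = np.empty(365)
    s_even = np.empty(365)
    for i in range(365):
        t_even[i], s_even[i] = _solve_evening_mode(
            t_night_true[i], t_break_true[i], params
        )

    truth = GroundTruth(
        city=city.name,
        year=year,
        t_night_true=np.where(np.arange(1, 366) == 365, np.nan, t_night_true),
        t_break_true=t_break_true,
        t_evening=t_even,
        sigma_evening=s_even,
        params=params,
    )

    n_users = len(users)
    if n_users == 0 or params.rate == 0:
        empty = pd.DataFrame({"user_id": pd.Series(dtype=str), "timestamp": pd.Series(dtype="datetime64[ns, UTC]")})
        return empty, truth

    user_ids = users["user_id"].to_numpy()
    burst_extra = params.burst_mean - 1.0
    p_act = params.p_active

    all_uid: list[np.ndarray] = []
    all_hours: list[np.ndarray] = []  # local hours since Jan 1 00:00
    for i in range(365):
        active = rng.random(n_users) < p_act
        ids = user_ids[active]
        if ids.size == 0:
            continue
        k = 1 + rng.poisson(burst_extra, size=ids.size)
        total = int(k.sum())
        is_morning = rng.random(total) < params.w_morning
        mu = np.where(is_morning, params.t_morning, t_even[i])
        sd = np.where(is_morning, params.sigma_morning, s_even[i])
        t = rng.normal(mu, sd)
        bad = (t < DAY_LO) | (t >= DAY_HI)
        while np.any(bad):  # resample the negligible out-of-day tail
            t[bad] = rng.normal(mu[bad], sd[bad])
            bad = (t < DAY_LO) | (t >= DAY_HI)
        all_uid.append(np.repeat(ids, k))
        all_hours.append(i * 24.0 + t)

    uid = np.concatenate(all_uid)
    local_hours = np.concatenate(all_hours)
    utc_ns = (
        np.datetime64(f"{year}-01-01T00:00:00", "ns").astype(np.int64)
        + ((local_hours - city.utc_offset) * 3.6e12).astype(np.int64)
    )
    ts = pd.to_datetime(utc_ns, utc=True)
    calls = pd.DataFrame({"user_id": uid, "timestamp": ts})
    calls = calls.sort_values("timestamp", kind="mergesort", ignore_index=True)
    return calls, truth
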