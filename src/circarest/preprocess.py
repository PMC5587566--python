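"""User filtering, logical-day assignment, binning and smoothing of call times.

The study population is restricted to subscribers who plausibly live in the
analysed city: the great-circle distance from the city centre to at least
one of their two home-location proxies (most-accessed cell tower, postal
centroid) must be under 15 km, the two proxies must be under 30 km apart,
and the age must lie in the closed interval [30, 75].

Call timestamps are mapped onto a *logical day* that runs from 04:00 to
03:59 local standard time, so the overnight low-activity period is not cut
in half at midnight.  Within a logical day, times live on the extended axis
[4, 28) hours; the morning window is [5, 16), the night window [17, 28)
(each 11 h = 132 five-minute bins), and the two one-hour gaps [4, 5) and
[16, 17) — the nocturnal and afternoon activity minima — belong to neither.

Histograms use left-closed right-open 5-minute bins anchored at the window
start; optional Savitzky-Golay smoothing (window 7, degree 4, mirror edges)
with negative values clipped to zero.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .solar import CityConfig

__all__ = [
    "EARTH_RADIUS_KM",
    "WINDOWS",
    "BIN_WIDTH_HOURS",
    "BinnedHistogram",
    "haversine_km",
    "assign_users_to_city",
    "filter_age",
    "logical_day",
    "daily_volumes",
    "detect_atypical_days",
    "bin_and_smooth",
]

EARTH_RADIUS_KM = 6371.0
BIN_WIDTH_HOURS = 5.0 / 60.0

#: Analysis windows on the extended [4, 28) hour axis.
WINDOWS: dict[str, tuple[float, float]] = {
    "full": (4.0, 28.0),
    "morning": (5.0, 16.0),
    "night": (17.0, 28.0),
}

SG_WINDOW = 7
SG_DEGREE = 4


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (spherical Earth, R = 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.deg2rad(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(a))


def assign_users_to_city(
    users: pd.DataFrame,
    city: CityConfig,
    max_center_km: float = 15.0,
    max_split_km: float = 30.0,
) -> pd.DataFrame:
    """Geographic residency filter.

    A user is accepted iff the nearer of their two locations (MACT, postal)
    is strictly under ``max_center_km`` from the city centre AND the two
    locations are strictly under ``max_split_km`` apart.  Rows with either
    location missing are discarded.  Returns the accepted rows.
    """
    cols = ["mact_lat", "mact_lon", "postal_lat", "postal_lon"]
    present = users.dropna(subset=cols)
    d_mact = haversine_km(city.latitude, city.longitude, present["mact_lat"], present["mact_lon"])
    d_postal = haversine_km(city.latitude, city.longitude, present["postal_lat"], present["postal_lon"])
    d_split = haversine_km(present["mact_lat"], present["mact_lon"], present["postal_lat"], present["postal_lon"])
    ok = (np.minimum(d_mact, d_postal) < max_center_km) & (d_split < max_split_km)
    return present.loc[np.asarray(ok)]


def filter_age(users: pd.DataFrame, lo: int = 30, hi: int = 75) -> pd.DataFrame:
    """Keep users with lo <= age <= hi (closed interval)."""
    return users.loc[(users["age"] >= lo) & (users["age"] <= hi)]


def logical_day(
    calls: pd.DataFrame, city: CityConfig, year: int
) -> tuple[pd.DataFrame, int]:
    """Map timestamps to (day index d, extended hour t in [4, 28)).

    Calls before 04:00 local standard time belong to the previous calendar
    day's logical day with t = clock + 24.  Calls whose logical day falls
    outside the study year are dropped; the count of dropped calls is
    returned alongside the mapped frame (columns user_id, d, t).
    """
    ts = pd.to_datetime(calls["timestamp"], utc=True)
    local = ts + pd.to_timedelta(city.utc_offset, unit="h")
    local = local.dt.tz_localize(None)
    t_clock = (
        local.dt.hour.to_numpy()
        + local.dt.minute.to_numpy() / 60.0
        + local.dt.second.to_numpy() / 3600.0
        + local.dt.microsecond.to_numpy() / 3.6e9
    )
    # logical day = calendar day of (local time - 4 h)
    shifted = local - pd.Timedelta(hours=4)
    jan1 = np.datetime64(f"{year}-01-01")
    d = (shifted.dt.floor("D").to_numpy() - jan1) / np.timedelta64(1, "D")
    d = d.astype(int) + 1
    t = np.where(t_clock < 4.0, t_clock + 24.0, t_clock)
    keep = (d >= 1) & (d <= 365)
    out = pd.DataFrame(
        {"user_id": calls["user_id"].to_numpy()[keep], "d": d[keep], "t": t[keep]}
    )
    return out, int((~keep).sum())


def daily_volumes(day_calls: pd.DataFrame) -> pd.Series:
    """Total call count per day index, reindexed over d = 1..365 (zeros filled)."""
    v = day_calls.groupby("d").size()
    return v.reindex(np.arange(1, 366), fill_value=0)


def detect_atypical_days(volumes: pd.Series, year: int, k: float = 5.0) -> set[int]:
    """Volume-outlier days, to stand in for the holiday/festivity exclusion.

    Day d is flagged iff |volume(d) - median over same weekday| > k * MAD,
    where the median and the (raw, unscaled) median absolute deviation are
    computed within each weekday class.  The set is *reported*; callers
    decide whether to exclude.  ``k = inf`` disables the filter.
    """
    if np.isinf(k):
        return set()
    jan1_wd = _dt.date(year, 1, 1).weekday()
    d = volumes.index.to_numpy()
    wd = (jan1_wd + d - 1) % 7
    vals = volumes.to_numpy(dtype=float)
    flagged: set[int] = set()
    for w in range(7):
        m = wd == w
        med = np.median(vals[m])
        mad = np.median(np.abs(vals[m] - med))
        dev = np.abs(vals[m] - med)
        bad = dev > k * mad
        flagged.update(int(x) for x in d[m][bad])
    return flagged


@dataclass
class BinnedHistogram:
    """5-minute binned (optionally smoothed) counts over one analysis window."""

    window: str
    edges: np.ndarray
    counts: np.ndarray
    smoothed: bool
    n_events: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def bin_and_smooth(times, window: str = "full", smooth: bool = False) -> BinnedHistogram:
    """Histogram call times into 5-min bins over a window, optionally smoothing.

    Bins are left-closed right-open, anchored at the window start; morning
    and night windows yield exactly 132 bins.  Smoothing is Savitzky-Golay
    (window 7, degree 4) with mirror padding, clipped at zero.  Times outside
    the window raise ``ValueError`` — callers must pre-split into windows.
    """
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}")
    lo, hi = WINDOWS[window]
    t = np.asarray(times, dtype=float)
    if t.size and (t.min() < lo or t.max() >= hi):
        raise ValueError(f"times outside window [{lo}, {hi})")
    n_bins = int(round((hi - lo) / BIN_WIDTH_HOURS))
    edges = lo + BIN_WIDTH_HOURS * np.arange(n_bins + 1)
    counts, _ = np.histogram(t, bins=edges)
    counts = counts.astype(float)
    if smooth:
        counts = savgol_filter(counts, SG_WINDOW, SG_DEGREE, mode="mirror")
        counts = np.clip(counts, 0.0, None)
    return BinnedHistogram(
        window=window, edges=edges, counts=counts, smoothed=smooth, n_events=int(t.size)
    )
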