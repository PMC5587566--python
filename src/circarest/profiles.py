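"""Daily activity profiles and the nocturnal resting statistic T_night.

Three per-city-day distributions are built from outgoing calls: P_all over
the full [4, 28) day, P_F over each user's *first* call in the morning
window, and P_L over each user's *last* call in the night window.  The
width of the nocturnal resting period is

    T_night(d) = 24 - (t_L(d) + s_L) + (t_F(d+1) - s_F)

where (t_L, s_L) are the mean and standard deviation of P_L of day d on the
extended axis (so values past midnight exceed 24) and (t_F, s_F) those of
P_F of the *following* morning.  Means and SDs are computed from the
smoothed, normalised histogram by default; the raw event list can be used
instead (``from_events=True`` in :func:`build_profile`).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import WINDOWS, BinnedHistogram, bin_and_smooth

__all__ = [
    "DailyActivityProfile",
    "first_last_events",
    "build_profile",
    "t_night",
    "weekday_labels",
    "weekly_aggregates",
]

#: Minimum number of events for a profile to be considered valid.
MIN_EVENTS = 50


@dataclass
class DailyActivityProfile:
    """Normalised activity distribution for one city-day and one call class."""

    kind: str  # "all", "first" or "last"
    histogram: BinnedHistogram
    probs: np.ndarray
    mean: float
    sd: float
    n_events: int
    valid: bool
    degenerate: bool = False


def first_last_events(day_calls: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-user first call of the morning and last call of the night, one day.

    ``day_calls`` holds one logical day (columns user_id, t on [4, 28)).
    Users without a call in a window contribute nothing to it; calls in the
    gaps [4, 5) and [16, 17) belong to neither window.
    """
    t = day_calls["t"].to_numpy()
    mlo, mhi = WINDOWS["morning"]
    nlo, nhi = WINDOWS["night"]
    morning = day_calls.loc[(t >= mlo) & (t < mhi)]
    night = day_calls.loc[(t >= nlo) & (t < nhi)]
    first = morning.groupby("user_id", sort=False)["t"].min().to_numpy()
    last = night.groupby("user_id", sort=False)["t"].max().to_numpy()
    return first, last


def build_profile(
    times,
    window: str,
    smooth: bool = True,
    min_events: int = MIN_EVENTS,
    kind: str = "all",
    from_events: bool = False,
) -> DailyActivityProfile:
    """Bin, smooth and normalise call times into a probability profile.

    The mean and SD are taken over bin centres weighted by the normalised
    (post-smoothing) mass, unless ``from_events`` asks for raw-event
    moments.  Profiles with fewer than ``min_events`` events are flagged
    invalid; a profile whose mass sits in a single bin is degenerate.
    """
    hist = bin_and_smooth(times, window=window, smooth=smooth)
    total = hist.counts.sum()
    valid = hist.n_events >= min_events and total > 0
    if total > 0:
        probs = hist.counts / total
    else:
        probs = np.zeros_like(hist.counts)
    if from_events:
        t = np.asarray(times, dtype=float)
        mean = float(t.mean()) if t.size else np.nan
        sd = float(t.std(ddof=0)) if t.size else np.nan
    else:
        c = hist.centers
        mean = float(np.sum(probs * c)) if total > 0 else np.nan
        var = float(np.sum(probs * (c - mean) ** 2)) if total > 0 else np.nan
        sd = float(np.sqrt(max(var, 0.0))) if total > 0 else np.nan
    degenerate = bool(total > 0 and np.count_nonzero(probs) <= 1)
    return DailyActivityProfile(
        kind=kind,
        histogram=hist,
        probs=probs,
        mean=mean,
        sd=sd,
        n_events=hist.n_events,
        valid=bool(valid),
        degenerate=degenerate,
    )


def t_night(
    last_profile: DailyActivityProfile | None,
    first_profile: DailyActivityProfile | None,
) -> float:
    """T_night = 24 - (t_L + s_L) + (t_F - s_F), hours; NaN if either side invalid.

    ``last_profile`` is day d's night profile (mean on (17, 28)),
    ``first_profile`` day d+1's morning profile (mean on (5, 16)).
    """
    if (
        last_profile is None
        or first_profile is None
        or not last_profile.valid
        or not first_profile.valid
    ):
        return float("nan")
    return float(
        24.0
        - (last_profile.mean + last_profile.sd)
        + (first_profile.mean - first_profile.sd)
    )


def weekday_labels(year: int, days: np.ndarray | None = None) -> np.ndarray:
    """Weekday index (0=Monday .. 6=Sunday) for each day index of the year."""
    if days is None:
        days = np.arange(1, 366)
    jan1 = _dt.date(year, 1, 1).weekday()
    return (jan1 + np.asarray(days) - 1) % 7


def weekly_aggregates(
    resting: pd.DataFrame, year: int, col: str = "t_night"
) -> pd.DataFrame:
    """Weekly Mon-Thu and Fri-Sun means of a resting series.

    ``resting`` has columns ``d`` and ``col`` (NaN = missing/excluded day).
    Weeks are calendar weeks starting Monday; means are over valid days
    only, NaN when a week has none.  Returns columns week, weekday_mean,
    weekend_mean.
    """
    d = resting["d"].to_numpy()
    wd = weekday_labels(year, d)
    jan1 = _dt.date(year, 1, 1).weekday()
    week = (d - 1 + jan1) // 7
    vals = resting[col].to_numpy(dtype=float)
    frame = pd.DataFrame({"week": week, "wd": wd, "v": vals})
    weekday = (
        frame.loc[frame["wd"] <= 3].groupby("week")["v"].mean().rename("weekday_mean")
    )
    weekend = (
        frame.loc[frame["wd"] >= 4].groupby("week")["v"].mean().rename("weekend_mean")
    )
    out = pd.concat([weekday, weekend], axis=1).reset_index()
    return out
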