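"""Sunrise, sunset and night length from solar geometry.

Night length ``N_length(d)`` — the time between sunset and sunrise — is the
seasonal covariate against which the nocturnal resting period is regressed.
It is computed per city and calendar day with the NOAA solar-calculator
algorithm (Meeus-style Julian-century polynomials for solar declination and
the equation of time, sunrise/sunset at the conventional -0.833 deg solar
altitude, i.e. geometric horizon plus standard atmospheric refraction).
Times are local *standard* time: the city's fixed UTC offset is applied and
daylight-saving shifts are deliberately ignored, so clock-time statistics
are comparable across the whole year.

The day index convention is d = 1 for January 1.  Polar latitudes (beyond
|66 deg|, where the sun may not rise or set) are not supported.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CityConfig",
    "NightLengthSeries",
    "UnsupportedLatitudeError",
    "sun_events",
    "night_length_series",
    "write_night_length_tsv",
]

#: Maximum supported absolute latitude, degrees.  Above this the -0.833 deg
#: altitude crossing can fail to exist (midnight sun / polar night).
MAX_LATITUDE = 66.0

#: Solar altitude at sunrise/sunset: 50 arc-minutes below the geometric
#: horizon (34' refraction + 16' solar semi-diameter).
ZENITH_DEG = 90.833


class UnsupportedLatitudeError(ValueError):
    """Latitude outside the supported band (polar day/night possible)."""


@dataclass(frozen=True)
class CityConfig:
    """A city: geographic location, clock offset and population."""

    name: str
    latitude: float  # degrees, +north
    longitude: float  # degrees, +east
    utc_offset: float  # hours ahead of UTC (standard time, no DST)
    population: int

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if self.population <= 0:
            raise ValueError("population must be positive")


@dataclass
class NightLengthSeries:
    """Per-day night length N_length(d) = 24 - daylight(d), in hours.

    ``values[i]`` holds N_length for day index d = i + 1; ``sunrise`` and
    ``sunset`` are local standard clock hours.
    """

    city: CityConfig
    year: int
    values: np.ndarray  # shape (365,)
    sunrise: np.ndarray = field(repr=False, default=None)
    sunset: np.ndarray = field(repr=False, default=None)

    @property
    def days(self) -> np.ndarray:
        return np.arange(1, self.values.size + 1)

    def value(self, d: int) -> float:
        """N_length for day index d (1-based)."""
        return float(self.values[d - 1])

    @property
    def daylight(self) -> np.ndarray:
        return 24.0 - self.values

    def argmax_day(self) -> int:
        return int(np.argmax(self.values)) + 1

    def argmin_day(self) -> int:
        return int(np.argmin(self.values)) + 1


def _julian_century(year: int, doy: np.ndarray, hours_utc: np.ndarray) -> np.ndarray:
    # JD of the proleptic-Gregorian ordinal: date.toordinal() + 1721424.5
    jd0 = _dt.date(year, 1, 1).toordinal() + 1721424.5
    jd = jd0 + (doy - 1.0) + hours_utc / 24.0
    return (jd - 2451545.0) / 36525.0


def _eqtime_decl(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equation of time (minutes) and solar declination (radians).

    NOAA solar-calculator polynomials in Julian centuries from J2000.
    """
    rad = np.deg2rad
    gml = np.mod(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    gma = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    seqc = (
        np.sin(rad(gma)) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + np.sin(rad(2 * gma)) * (0.019993 - 0.000101 * t)
        + np.sin(rad(3 * gma)) * 0.000289
    )
    stl = gml + seqc
    omega = 125.04 - 1934.136 * t
    sal = stl - 0.00569 - 0.00478 * np.sin(rad(omega))
    moe = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    oc = moe + 0.00256 * np.cos(rad(omega))
    decl = np.arcsin(np.sin(rad(oc)) * np.sin(rad(sal)))
    vary = np.tan(rad(oc / 2.0)) ** 2
    eqtime = 4.0 * np.rad2deg(
        vary * np.sin(2 * rad(gml))
        - 2.0 * ecc * np.sin(rad(gma))
        + 4.0 * ecc * vary * np.sin(rad(gma)) * np.cos(2 * rad(gml))
        - 0.5 * vary * vary * np.sin(4 * rad(gml))
        - 1.25 * ecc * ecc * np.sin(2 * rad(gma))
    )
    return eqtime, decl


def _events_utc(
    latitude: float, longitude: float, year: int, doy: np.ndarray, n_refine: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Sunrise/sunset in fractional UTC hours for the given days.

    The hour angle is first evaluated at local noon, then refined by
    re-evaluating declination and the equation of time at the current
    event-time estimate (the standard NOAA two-pass refinement).  Without
    the refinement the solstice-day ordering of near-tied neighbours is not
    resolved correctly.
    """
    latr = np.deg2rad(latitude)
    cos_zen = np.cos(np.deg2rad(ZENITH_DEG))

    def solve(hours_utc: np.ndarray, rise: bool) -> np.ndarray:
        t = _julian_century(year, doy, hours_utc)
        eqtime, decl = _eqtime_decl(t)
        cosha = cos_zen / (np.cos(latr) * np.cos(decl)) - np.tan(latr) * np.tan(decl)
        if np.any(cosha < -1.0) or np.any(cosha > 1.0):
            raise UnsupportedLatitudeError(
                f"sun does not cross the horizon at latitude {latitude}"
            )
        ha = np.rad2deg(np.arccos(cosha))
        sign = 1.0 if rise else -1.0
        return (720.0 - 4.0 * (longitude + sign * ha) - eqtime) / 60.0

    noon = np.full(np.shape(doy), 12.0 - longitude / 15.0)
    sr = solve(noon, rise=True)
    ss = solve(noon, rise=False)
    for _ in range(n_refine):
        sr = solve(sr, rise=True)
        ss = solve(ss, rise=False)
    return sr, ss


def _check_latitude(latitude: float) -> None:
    if abs(latitude) >= MAX_LATITUDE:
        raise UnsupportedLatitudeError(
            f"|latitude| = {abs(latitude)} >= {MAX_LATITUDE} deg is not supported"
        )


def sun_events(city: CityConfig, date: _dt.date) -> tuple[float, float]:
    """Sunrise and sunset as local standard clock hours for one date.

    Returns ``(sunrise, sunset)`` with ``0 <= sunrise < sunset < 24`` for
    cities whose UTC offset is consistent with their longitude.
    """
    _check_latitude(city.latitude)
    doy = np.array([float(date.timetuple().tm_yday)])
    sr, ss = _events_utc(city.latitude, city.longitude, date.year, doy)
    return float(sr[0] + city.utc_offset), float(ss[0] + city.utc_offset)


def night_length_series(city: CityConfig, year: int) -> NightLengthSeries:
    """N_length(d) = 24 - (sunset(d) - sunrise(d)) for every day of a non-leap year.

    Each day's night length is derived from that day's own sunrise and
    sunset (not the sunset-to-next-sunrise span); the difference is below
    two minutes per day at mid latitudes.
    """
    _check_latitude(city.latitude)
    if _dt.date(year, 12, 31).timetuple().tm_yday != 365:
        raise ValueError(f"{year} is a leap year; only 365-day years are supported")
    doy = np.arange(1, 366, dtype=float)
    sr, ss = _events_utc(city.latitude, city.longitude, year, doy)
    daylight = ss - sr
    return NightLengthSeries(
        city=city,
        year=year,
        values=24.0 - daylight,
        sunrise=sr + city.utc_offset,
        sunset=ss + city.utc_offset,
    )


def write_night_length_tsv(series: NightLengthSeries, path) -> None:
    """TSV with columns city, d, date, sunrise, sunset, n_length_hours."""
    import pandas as pd

    d = series.days
    dates = [
        (_dt.date(series.year, 1, 1) + _dt.timedelta(days=int(i) - 1)).isoformat()
        for i in d
    ]
    frame = pd.DataFrame(
        {
            "city": series.city.name,
            "d": d,
            "date": dates,
            "sunrise": np.round(series.sunrise, 4),
            "sunset": np.round(series.sunset, 4),
            "n_length_hours": np.round(series.values, 6),
        }
    )
    frame.to_csv(path, sep="\t", index=False)
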