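"""Low-precision solar geometry.

Implements the standard low-precision solar position algorithm (Meeus-style,
as used in the NOAA solar calculator): solar declination, equation of time,
and apparent solar altitude for a given UTC time and position.  Accuracy is a
few hundredths of a degree in declination and well under 0.3 degrees in
altitude over 1990-2050, which is far below the error floor of light-level
geolocation (5-min light bins correspond to >1 degree of longitude).

All angles are in degrees, times are UTC.  Functions are vectorized over
time: they accept scalars, numpy ``datetime64`` arrays or pandas
``DatetimeIndex`` objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "declination",
    "equation_of_time",
    "solar_position",
    "solar_altitude",
    "solar_noon_utc",
    "sunrise_sunset",
    "equinox_dates",
]

_J2000 = np.datetime64("2000-01-01T12:00:00", "s")


def _julian_century(time) -> np.ndarray:
    """Julian centuries since J2000.0 for UTC times (UT1~UTC is fine here)."""
    t = np.asarray(pd.to_datetime(time).to_numpy() if not isinstance(time, np.ndarray) else time)
    t = t.astype("datetime64[s]")
    days = (t - _J2000) / np.timedelta64(86400, "s")
    return days.astype(float) / 36525.0


def _solar_coords(T: np.ndarray):
    """Geometric solar coordinates at Julian century T.

    Returns (declination deg, equation of time minutes).
    """
    rad = np.deg2rad
    L0 = np.mod(280.46646 + T * (36000.76983 + T * 0.0003032), 360.0)
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    C = (
        np.sin(rad(M)) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(rad(2 * M)) * (0.019993 - 0.000101 * T)
        + np.sin(rad(3 * M)) * 0.000289
    )
    true_long = L0 + C
    omega = 125.04 - 1934.136 * T
    lam = true_long - 0.00569 - 0.00478 * np.sin(rad(omega))
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * np.cos(rad(omega))

    decl = np.rad2deg(np.arcsin(np.sin(rad(eps)) * np.sin(rad(lam))))

    y = np.tan(rad(eps / 2.0)) ** 2
    eot_rad = (
        y * np.sin(2 * rad(L0))
        - 2 * e * np.sin(rad(M))
        + 4 * e * y * np.sin(rad(M)) * np.cos(2 * rad(L0))
        - 0.5 * y * y * np.sin(4 * rad(L0))
        - 1.25 * e * e * np.sin(2 * rad(M))
    )
    eot_min = 4.0 * np.rad2deg(eot_rad)
    return decl, eot_min


def declination(time):
    """Solar declination (degrees) at UTC time(s)."""
    return _solar_coords(_julian_century(time))[0]


def equation_of_time(time):
    """Equation of time (minutes, apparent minus mean solar time) at UTC time(s)."""
    return _solar_coords(_julian_century(time))[1]


def _utc_minutes_of_day(time) -> np.ndarray:
    t = np.asarray(pd.to_datetime(time).to_numpy() if not isinstance(time, np.ndarray) else time)
    t = t.astype("datetime64[s]")
    day = t.astype("datetime64[D]").astype("datetime64[s]")
    return (t - day) / np.timedelta64(60, "s")


def solar_position(time, lon, lat):
    """Apparent solar altitude plus declination and equation of time.

    Parameters
    ----------
    time : scalar or array of UTC times
    lon, lat : degrees (scalar or arrays broadcastable against time)

    Returns
    -------
    (altitude_deg, declination_deg, equation_of_time_min)
    """
    T = _julian_century(time)
    decl, eot = _solar_coords(T)
    tst = np.mod(_utc_minutes_of_day(time) + eot + 4.0 * np.asarray(lon, float), 1440.0)
    hour_angle = tst / 4.0 - 180.0
    rad = np.deg2rad
    lat = np.asarray(lat, float)
    sin_alt = (
        np.sin(rad(lat)) * np.sin(rad(decl))
        + np.cos(rad(lat)) * np.cos(rad(decl)) * np.cos(rad(hour_angle))
    )
    alt = np.rad2deg(np.arcsin(np.clip(sin_alt, -1.0, 1.0)))
    return alt, decl, eot


def solar_altitude(time, lon, lat):
    """Apparent solar altitude (degrees)."""
    return solar_position(time, lon, lat)[0]


def solar_noon_utc(date, lon):
    """UTC hour (float) of local apparent solar noon on ``date`` at ``lon``."""
    approx = pd.Timestamp(date) + pd.Timedelta(hours=12)
    eot = equation_of_time(approx)
    return 12.0 - eot / 60.0 - np.asarray(lon, float) / 15.0


def sunrise_sunset(date, lon, lat, altitude=-0.833):
    """UTC times of threshold-altitude sunrise/sunset on a UTC date.

    Uses the day-length equation ``cos H0 = (sin a - sin lat sin d) /
    (cos lat cos d)``.  Returns ``(sunrise, sunset)`` as pandas Timestamps, or
    ``(None, None)`` when the sun never crosses ``altitude`` that day.
    """
    rad = np.deg2rad
    base = pd.Timestamp(date)
    sunrise = sunset = base + pd.Timedelta(hours=12)
    for _ in range(2):  # refine: declination/EoT drift over the half day
        out = []
        for ref in (sunrise, sunset):
            d = float(declination(ref))
            cos_h0 = (np.sin(rad(altitude)) - np.sin(rad(lat)) * np.sin(rad(d))) / (
                np.cos(rad(lat)) * np.cos(rad(d))
            )
            if not -1.0 < cos_h0 < 1.0:
                return None, None
            h0 = np.rad2deg(np.arccos(cos_h0))
            eot = float(equation_of_time(ref))
            noon_h = 12.0 - eot / 60.0 - lon / 15.0
            sign = -1.0 if ref is sunrise else 1.0
            out.append(base + pd.Timedelta(hours=noon_h + sign * h0 / 15.0))
        sunrise, sunset = out
    return sunrise, sunset


def equinox_dates(year: int):
    """UTC timestamps of the two declination zero-crossings in ``year``.

    The March crossing is south-to-north, the September one north-to-south;
    both are located by root-finding the declination on the UTC timeline, so
    the equinox-exclusion window is self-consistent with the solar model used
    for latitude estimation.
    """
    out = []
    for guess in (f"{year}-03-20", f"{year}-09-22"):
        t0 = pd.Timestamp(guess) - pd.Timedelta(days=5)

        def f(days):
            return float(declination(t0 + pd.Timedelta(days=float(days))))

        root = brentq(f, 0.0, 10.0, xtol=1e-6)
        out.append(t0 + pd.Timedelta(days=float(root)))
    return tuple(out)
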