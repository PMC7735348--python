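"""Track filtering and geometry for twice-daily geolocation fixes.

Equinox flagging (latitude is unidentifiable from day length for ~2 weeks
either side of each equinox), the 1500 km/day speed rule, great-circle
distance, longitudinal change-point timing (used when departure or arrival
falls inside an equinox window), and the per-trip distance metrics
(maximum range from the colony and total distance travelled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import solar

__all__ = [
    "GeoPoint",
    "great_circle_km",
    "flag_equinox",
    "speed_filter",
    "longitudinal_changepoint",
    "Changepoint",
    "track_metrics",
    "wrap_lon",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0


class GeoPoint(NamedTuple):
    lat: float
    lon: float


def usable_fixes(track: pd.DataFrame) -> pd.DataFrame:
    """Rows usable for spatial analysis: kept, with a reliable latitude."""
    mask = (track.get("flag", "kept") == "kept") & track["lat"].notna()
    if "lat_reliable" in track:
        mask &= track["lat_reliable"].astype(bool)
    return track[mask]


def wrap_lon(lon):
    """Wrap longitudes to (-180, 180]."""
    lon = np.asarray(lon, float)
    out = -(np.mod(-lon + 180.0, 360.0) - 180.0)
    return out if out.ndim else float(out)


def great_circle_km(lat1, lon1, lat2=None, lon2=None):
    """Haversine great-circle distance in km (R = 6371.0), vectorized.

    Accepts either four scalar/array arguments or two ``GeoPoint``-like
    pairs: ``great_circle_km(p, q)``.
    """
    if lat2 is None:  # (p, q) call style
        (lat1, lon1), (lat2, lon2) = lat1, lon1
    rad = np.deg2rad
    phi1, phi2 = rad(np.asarray(lat1, float)), rad(np.asarray(lat2, float))
    dphi = phi2 - phi1
    dlam = rad(np.asarray(lon2, float)) - rad(np.asarray(lon1, float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def equinox_windows(years, half_width_days: int = 14):
    """[(start, end)] closed windows around each computed equinox in ``years``."""
    wins = []
    for y in np.unique(np.atleast_1d(years)):
        for eq in solar.equinox_dates(int(y)):
            wins.append((eq - pd.Timedelta(days=half_width_days), eq + pd.Timedelta(days=half_width_days)))
    return wins


def in_equinox_window(times, years=None, half_width_days: int = 14):
    """Boolean mask: |t - equinox| <= half_width_days (window closed at 14 d)."""
    t = pd.DatetimeIndex(times)
    if years is None:
        years = sorted(set(t.year))
    mask = np.zeros(len(t), bool)
    for lo, hi in equinox_windows(years, half_width_days):
        mask |= (t >= lo.normalize()) & (t < (hi + pd.Timedelta(days=1)).normalize())
    return mask


def flag_equinox(positions: pd.DataFrame, half_width_days: int = 14) -> pd.DataFrame:
    """Flag positions within two weeks of an equinox.

    Adds/updates a ``flag`` column: rows inside the window become
    ``equinox_excluded`` (their latitude is dropped from spatial use;
    longitude is retained for change-point timing) and ``lat_reliable`` is
    forced False.  Other rows keep flag ``kept``.
    """
    out = positions.copy()
    if "flag" not in out:
        out["flag"] = "kept"
    t = pd.DatetimeIndex(out["time"])
    mask = in_equinox_window(t, half_width_days=half_width_days)
    out.loc[mask, "flag"] = "equinox_excluded"
    if "lat_reliable" in out:
        out.loc[mask, "lat_reliable"] = False
    else:
        out["lat_reliable"] = ~mask
    return out


def speed_filter(positions: pd.DataFrame, v_max_kmday: float = 1500.0) -> pd.DataFrame:
    """Forward single-pass speed filter on the kept, latitude-reliable fixes.

    Starting from the first usable fix, any fix whose implied speed from the
    last *kept* fix exceeds ``v_max_kmday`` is flagged ``speed_excluded``.
    Deterministic; the unrealistic-speed rule is the only spike removal.
    """
    out = positions.copy()
    if "flag" not in out:
        out["flag"] = "kept"
    usable = (out["flag"] == "kept") & out.get("lat_reliable", True) & out["lat"].notna()
    idx = out.index[usable]
    if len(idx) == 0:
        raise ValueError("track degenerate: no usable positions")
    last = idx[0]
    n_dropped = 0
    for i in idx[1:]:
        dt_days = (out.at[i, "time"] - out.at[last, "time"]).total_seconds() / 86400.0
        if dt_days <= 0:
            continue
        d = great_circle_km(out.at[last, "lat"], out.at[last, "lon"], out.at[i, "lat"], out.at[i, "lon"])
        if d / dt_days > v_max_kmday:
            out.at[i, "flag"] = "speed_excluded"
            n_dropped += 1
        else:
            last = i
    out.attrs["n_speed_excluded"] = n_dropped
    if (out["flag"] == "kept").sum() == 0:
        raise ValueError("track degenerate: all positions dropped")
    return out


@dataclass(frozen=True)
class Changepoint:
    """Longitudinal movement timing.

    ``trigger``: first date on which |lon - colony_lon| > min_shift has held
    (and keeps holding) for ``persistence`` consecutive days.
    ``onset``: the day after the last near-colony-longitude day before the
    trigger — the back-dated movement start used for phenology.
    """

    trigger: pd.Timestamp
    onset: pd.Timestamp


def longitudinal_changepoint(daily_lon: pd.Series, colony_lon: float,
                             min_shift_deg: float = 5.0, persistence_days: int = 3,
                             reverse: bool = False) -> Changepoint | None:
    """Departure (or, with ``reverse=True``, arrival) from raw daily longitudes.

    ``daily_lon`` is a date-indexed series (raw longitudes, equinox days
    included — longitude is unaffected by the latitude degeneracy).
    Returns None when the shift never persists.
    """
    s = daily_lon.dropna().sort_index()
    if len(s) < persistence_days:
        return None
    shift = np.abs(wrap_lon(np.asarray(s.values, float) - colony_lon))
    if reverse:
        shift = shift[::-1]
    ij = _scan_changepoint(shift, min_shift_deg, persistence_days)
    if ij is None:
        return None
    trigger_i, onset_i = ij
    if reverse:
        n = len(s)
        trigger_i, onset_i = n - 1 - trigger_i, n - 1 - onset_i
    return Changepoint(trigger=s.index[trigger_i], onset=s.index[onset_i])


def _scan_changepoint(shift: np.ndarray, min_shift_deg: float, persistence_days: int):
    """Positional (trigger, onset) indices on a |Delta lon| series, or None."""
    beyond = shift > min_shift_deg
    run = 0
    trigger_i = None
    for i, b in enumerate(beyond):
        run = run + 1 if b else 0
        if run >= persistence_days:
            trigger_i = i - persistence_days + 1
            break
    if trigger_i is None:
        return None
    near_idx = np.flatnonzero(shift[: trigger_i + 1] <= min_shift_deg / 2.0)
    onset_i = min(near_idx[-1] + 1, trigger_i) if len(near_idx) else trigger_i
    return trigger_i, onset_i


def _smooth_positions(lat: np.ndarray, lon: np.ndarray):
    """3-position running median of lat/lon (lon unwrapped first)."""
    lat_s = pd.Series(lat).rolling(3, center=True, min_periods=1).median().to_numpy()
    lon_u = np.rad2deg(np.unwrap(np.deg2rad(lon)))
    lon_s = pd.Series(lon_u).rolling(3, center=True, min_periods=1).median().to_numpy()
    return lat_s, wrap_lon(lon_s)


def track_metrics(track: pd.DataFrame, colony, window=None) -> dict:
    """Trip geometry over the kept fixes.

    Returns ``max_range_km`` / ``total_distance_km`` from the raw kept fixes
    (path sums over raw geolocator fixes are inflated by position jitter, but
    this matches how such totals are conventionally reported) plus
    ``*_smoothed`` variants computed after a 3-position running median of
    lat/lon — the variant used for parameter-recovery checks.  Equinox gaps
    are bridged by the single segment between the kept fixes either side.
    """
    colony = GeoPoint(*colony)
    kept = usable_fixes(track)
    if window is not None:
        t = pd.DatetimeIndex(kept["time"])
        kept = kept[(t >= pd.Timestamp(window[0])) & (t <= pd.Timestamp(window[1]) + pd.Timedelta(days=1))]
    if len(kept) < 2:
        raise ValueError("need >= 2 kept positions in window")
    lat = kept["lat"].to_numpy(float)
    lon = kept["lon"].to_numpy(float)
    rng_km = great_circle_km(colony.lat, colony.lon, lat, lon)
    total = float(great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:]).sum())
    lat_s, lon_s = _smooth_positions(lat, lon)
    rng_s = great_circle_km(colony.lat, colony.lon, lat_s, lon_s)
    total_s = float(great_circle_km(lat_s[:-1], lon_s[:-1], lat_s[1:], lon_s[1:]).sum())
    return {
        "max_range_km": float(rng_km.max()),
        "total_distance_km": total,
        "max_range_smoothed_km": float(rng_s.max()),
        "total_distance_smoothed_km": total_s,
        "n_positions": int(len(kept)),
    }
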