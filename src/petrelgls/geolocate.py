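"""Threshold-method light-level geolocation.

Twilight events are threshold crossings of the recorded light curve; a
dawn-dusk pair gives a noon-anchored position, a dusk-dawn pair a
midnight-anchored one, so a full day yields two positions.  Longitude comes
from the timing of local apparent noon/midnight (via the equation of time);
latitude from the day (or night) length through the sunrise equation

    sin(a0) = sin(lat) sin(decl) + cos(lat) cos(decl) cos(H),

solved for latitude by bracketed root-finding, where ``a0`` is the
calibrated sun-altitude threshold and ``H`` the half-day hour angle.  Near
the equinoxes the equation is degenerate (day length ~12 h at every
latitude) and latitude is flagged unreliable; longitude is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import solar
from .track import wrap_lon

__all__ = [
    "Calibration",
    "detect_twilights",
    "calibrate_sun_altitude",
    "estimate_positions",
    "latitude_from_daylength",
    "longitude_from_transit",
]

_BIN = pd.Timedelta(minutes=5)
_MERGE = pd.Timedelta(minutes=30)


@dataclass(frozen=True)
class Calibration:
    """In-habitat calibration of the threshold method."""

    sun_altitude_deg: float  # a0, the solar altitude at threshold crossings
    light_threshold: float  # device units
    window: tuple  # (start, end) of the calibration period
    colony: tuple  # (lat, lon) of the known calibration position
    n_twilights: int = 0


def detect_twilights(light: pd.DataFrame, light_threshold: float) -> pd.DataFrame:
    """Interpolated threshold crossings of a max-per-5-min light series.

    A rising crossing is a dawn, a falling one a dusk.  Because each bin
    stores the maximum over its 5 minutes, a rising signal's bin value is
    attained at the bin *end* and a falling signal's at the bin *start*;
    crossing times are linearly interpolated between the correspondingly
    timestamped bins, which removes the half-bin bias of midpoint stamping.

    Spurious crossing pairs from brief daytime shading (a dusk immediately
    followed by a dawn, or vice versa, within 60 min) are removed, then
    same-kind crossings within 30 min are merged (flagged ``interrupted``).

    Returns a DataFrame with columns ``time``, ``kind`` ("dawn"/"dusk"),
    ``quality`` ("ok"/"interrupted").
    """
    v = light["max_light"].to_numpy(float)
    t = pd.DatetimeIndex(light["bin_start"])
    if not (v.min() < light_threshold <= v.max()):
        raise ValueError("uninformative threshold: outside observed light range")
    above = v >= light_threshold
    rise = ~above[:-1] & above[1:]
    fall = above[:-1] & ~above[1:]

    events = []
    for idx in np.flatnonzero(rise):
        frac = (light_threshold - v[idx]) / (v[idx + 1] - v[idx])
        events.append((t[idx] + _BIN + frac * _BIN, "dawn"))  # between bin ends
    for idx in np.flatnonzero(fall):
        frac = (light_threshold - v[idx]) / (v[idx + 1] - v[idx])
        events.append((t[idx] + frac * _BIN, "dusk"))  # between bin starts
    events.sort(key=lambda e: e[0])
    if not events:
        return pd.DataFrame(columns=["time", "kind", "quality"])

    # shading guard 1: a brief dip (dusk then dawn) or blip (dawn then dusk)
    # bounds a spurious light segment; repeatedly drop the bounding pair of
    # the shortest such segment under 60 min, so a true crossing truncated by
    # a shaded bin survives while the shading artifact itself is removed.
    while len(events) >= 2:
        gaps = [
            (events[i + 1][0] - events[i][0], i)
            for i in range(len(events) - 1)
            if events[i][1] != events[i + 1][1]
        ]
        if not gaps:
            break
        gap, i = min(gaps)
        if gap >= 2 * _MERGE:
            break
        del events[i : i + 2]

    # shading guard 2: merge same-kind crossings within 30 min
    merged: list[list] = []
    for ev in events:
        if merged and merged[-1][1] == ev[1] and (ev[0] - merged[-1][0]) <= _MERGE:
            if ev[1] == "dusk":
                merged[-1][0] = ev[0]  # keep last falling crossing
            merged[-1][2] = "interrupted"
        else:
            merged.append([ev[0], ev[1], "ok"])

    # enforce strict alternation: of same-kind neighbours keep the cleaner one
    out: list[list] = []
    for ev in merged:
        if out and out[-1][1] == ev[1]:
            if out[-1][2] == "interrupted" and ev[2] == "ok":
                out[-1] = ev
            continue
        out.append(ev)
    return pd.DataFrame(out, columns=["time", "kind", "quality"])


def calibrate_sun_altitude(light: pd.DataFrame, colony, window,
                           light_threshold: float) -> Calibration:
    """Calibrate the sun-altitude threshold at a known position.

    ``a0`` is the median solar altitude, computed at the colony, over all
    clean twilight crossing times inside the calibration window (which must
    span at least 5 days at the known position).
    """
    lat, lon = colony
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    sel = light[(pd.DatetimeIndex(light["bin_start"]) >= lo) & (pd.DatetimeIndex(light["bin_start"]) <= hi)]
    tw = detect_twilights(sel, light_threshold) if len(sel) else pd.DataFrame(columns=["time", "kind", "quality"])
    tw = tw[tw["quality"] == "ok"]
    if len(tw) < 5:
        raise ValueError("insufficient calibration data: fewer than 5 usable twilights")
    alts = solar.solar_altitude(pd.DatetimeIndex(tw["time"]), lon, lat)
    return Calibration(
        sun_altitude_deg=float(np.median(alts)),
        light_threshold=light_threshold,
        window=(lo, hi),
        colony=(lat, lon),
        n_twilights=int(len(tw)),
    )


def longitude_from_transit(t_mid: pd.Timestamp, eot_minutes: float, anchor: str = "noon") -> float:
    """Longitude (degrees, wrapped to (-180, 180]) from a solar transit time.

    Local apparent noon occurs at UTC hour ``12 - EoT/60 - lon/15``; the
    midnight anchor is shifted by 12 h.
    """
    h = t_mid.hour + t_mid.minute / 60.0 + t_mid.second / 3600.0
    ref = 12.0 if anchor == "noon" else 24.0
    return float(wrap_lon(15.0 * (ref - eot_minutes / 60.0 - h)))


def latitude_from_daylength(half_angle_deg: float, decl_deg: float, a0_deg: float,
                            prev_lat: float, tol_h_deg: float = 0.75,
                            max_band_deg: float = 10.0) -> tuple[float | None, bool]:
    """Solve sin a0 = sin(lat) sin(d) + cos(lat) cos(d) cos(H) for latitude.

    Roots are bracketed on a 0.5-degree scan of [-89, 89] and refined with
    Brent's method; with two roots the one nearer ``prev_lat`` wins (the
    continuity rule, seeded by the colony latitude).

    Returns (lat, reliable); reliable is False when no root exists,
    |declination| < 1.5 degrees, or the equation is degenerate at twilight
    noise scale: the band of latitudes whose predicted half-day hour angle
    lies within ``tol_h_deg`` of the observed one (0.75 deg of hour angle is
    ~6 min of day length, a couple of twilight-timing standard errors) is
    wider than ``max_band_deg``.  Near the equinoxes the day-length curve is
    almost flat in latitude, so this band spans tens of degrees — the same
    pathology that motivates the calendar equinox exclusion, which persists
    a few extra days at high latitudes.
    """
    rad = np.deg2rad
    sa0, sd, cd, ch = np.sin(rad(a0_deg)), np.sin(rad(decl_deg)), np.cos(rad(decl_deg)), np.cos(rad(half_angle_deg))

    def f(phi):
        return np.sin(rad(phi)) * sd + np.cos(rad(phi)) * cd * ch - sa0

    grid = np.arange(-89.0, 89.0 + 1e-9, 0.5)
    vals = f(grid)
    roots = []
    for i in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
        roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-6))
    for i in np.flatnonzero(vals == 0.0):
        roots.append(float(grid[i]))
    if not roots:
        return None, False
    lat = min(roots, key=lambda r: abs(r - prev_lat))
    reliable = abs(decl_deg) >= 1.5
    if reliable:
        arg = (sa0 - np.sin(rad(grid)) * sd) / (np.cos(rad(grid)) * cd)
        with np.errstate(invalid="ignore"):
            h_pred = np.rad2deg(np.arccos(np.clip(arg, -1.0, 1.0)))
            h_pred[np.abs(arg) > 1.0] = np.nan
        band = np.nansum(np.abs(h_pred - half_angle_deg) <= tol_h_deg) * 0.5
        if band > max_band_deg:
            reliable = False
    return float(lat), reliable


def estimate_positions(twilights: pd.DataFrame, cal: Calibration) -> pd.DataFrame:
    """Twice-daily positions from alternating twilights.

    Each dawn-dusk pair yields a noon-anchored estimate, each dusk-dawn pair
    a midnight-anchored one (reusing the preceding dusk), giving at most two
    positions per day.  Columns: ``time`` (anchor midpoint), ``anchor``,
    ``lon``, ``lat``, ``lat_reliable``; unreliable rows carry longitude only
    when the latitude equation has no usable root.
    """
    tw = twilights.sort_values("time").reset_index(drop=True)
    rows = []
    # continuity anchor: median of the last few accepted latitudes, with a
    # jump allowance that grows with the time since the last accepted fix
    # (so a single bad fix cannot walk the anchor away, and the anchor
    # recovers after an equinox gap)
    recent: list[tuple[pd.Timestamp, float]] = [(None, cal.colony[0])]
    for i in range(len(tw) - 1):
        k1, k2 = tw.at[i, "kind"], tw.at[i + 1, "kind"]
        if k1 == k2:
            continue  # unpaired twilight: skipped
        t1, t2 = tw.at[i, "time"], tw.at[i + 1, "time"]
        span_h = (t2 - t1).total_seconds() / 3600.0
        if not 0.0 < span_h < 22.0:
            continue
        t_mid = t1 + (t2 - t1) / 2
        _, decl, eot = solar.solar_position(t_mid, 0.0, 0.0)
        anchor = "noon" if k1 == "dawn" else "midnight"
        lon = longitude_from_transit(t_mid, float(eot), anchor)
        day_h = span_h if anchor == "noon" else 24.0 - span_h
        half_angle = 15.0 * day_h / 2.0
        lat_anchor = float(np.median([la for _, la in recent[-5:]]))
        lat, reliable = latitude_from_daylength(half_angle, float(decl), cal.sun_altitude_deg, lat_anchor)
        if reliable and lat is not None:
            last_t = recent[-1][0]
            gap_days = (t_mid - last_t).total_seconds() / 86400.0 if last_t is not None else 1.0
            if abs(lat - lat_anchor) > 6.0 + 2.0 * gap_days:
                reliable = False  # implausible latitudinal jump: degenerate solution
            else:
                recent.append((t_mid, lat))
        rows.append(
            {
                "time": t_mid,
                "anchor": anchor,
                "lon": lon,
                "lat": lat if lat is not None else np.nan,
                "lat_reliable": bool(reliable and lat is not None),
            }
        )
    return pd.DataFrame(rows, columns=["time", "anchor", "lon", "lat", "lat_reliable"])
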