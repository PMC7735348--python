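"""Synthetic GLS birds: ground-truth itineraries, sensor streams, feathers.

A simulated bird lives through the post-breeding phase structure of a
burrow-nesting seabird: nightly burrow attendance at the colony, a fast
outward travel leg to a distal residency area, a long residency with local
wandering (during which a quasi-flightless wing-moult block occurs), an
inward leg, and renewed attendance at the colony.  From the 1-min itinerary
three device streams are rendered the way archival geolocators record them:

* light — max over 5-min bins of a logistic function of solar altitude,
  with multiplicative noise and occasional shading; burrow minutes are dark;
* immersion — 30-s wet/dry samples counted per 4-h (or 10-min) bin;
* temperature — max over 4-h bins of 5-min samples, elevated in the burrow.

Feather stable-isotope values are drawn from a linear latitude isoscape at
the bird's true position on each feather's grow date.

The defaults describe a subantarctic colony (Kerguelen-like, 49.47S 69.95E)
whose birds depart in late February, travel ~2450 km south-west at
170 km/day, reside ~6 months near 64S, moult 35 days after departure and
return in late September.  Identical (config, seed) pairs give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as _date

import numpy as np
import pandas as pd

from . import solar
from .track import great_circle_km

__all__ = [
    "Isoscape",
    "SimConfig",
    "TrueItinerary",
    "SimBird",
    "simulate_itinerary",
    "render_light",
    "render_immersion",
    "render_temperature",
    "render_feathers",
    "simulate_bird",
    "cohort_configs",
    "light_transfer",
    "LIGHT_DARK",
    "LIGHT_SAT",
    "DEFAULT_LIGHT_THRESHOLD",
]

# behaviour state codes
BURROW, FLIGHT, ON_WATER, MOULT_ON_WATER = 0, 1, 2, 3
STATE_NAMES = {BURROW: "burrow", FLIGHT: "flight", ON_WATER: "on_water", MOULT_ON_WATER: "moult_on_water"}

# light transfer function: logistic in solar altitude, clamped to a dark
# floor below -9 deg and saturation above +3 deg (single monotone crossing
# per twilight).
LIGHT_DARK = 1.0
LIGHT_SAT = 64.0
_ALT_DARK, _ALT_SAT = -9.0, 3.0
_ALT_MID, _ALT_SCALE = -3.0, 1.0


def light_transfer(altitude):
    """Noise-free recorded light as a function of solar altitude (degrees)."""
    a = np.clip(np.asarray(altitude, float), _ALT_DARK, _ALT_SAT)
    return LIGHT_DARK + (LIGHT_SAT - LIGHT_DARK) / (1.0 + np.exp(-(a - _ALT_MID) / _ALT_SCALE))


#: light value at the -6 deg sun altitude crossing of the transfer function;
#: using this threshold makes the true calibration angle exactly -6 deg.
DEFAULT_LIGHT_THRESHOLD = float(light_transfer(-6.0))


@dataclass(frozen=True)
class Isoscape:
    """Linear latitude isoscapes for feather d13C / d15N (permil).

    Defaults put the -19.5 permil d13C isocline (the feather proxy of the
    Polar Front) at 52S and the 9.9 permil d15N isocline at the same
    latitude, with gradients that reproduce the observed subantarctic-to-
    subtropical spread of Southern Ocean feather values.
    """

    d13c_intercept: float = 3.9
    d13c_slope: float = 0.45  # permil per degree latitude (signed degrees)
    d13c_sd: float = 1.0
    d15n_intercept: float = 28.1
    d15n_slope: float = 0.35
    d15n_sd: float = 1.2

    def d13c_mean(self, lat):
        return self.d13c_intercept + self.d13c_slope * np.asarray(lat, float)

    def d15n_mean(self, lat):
        return self.d15n_intercept + self.d15n_slope * np.asarray(lat, float)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated bird-season."""

    colony_lat: float = -49.47
    colony_lon: float = 69.95
    season_start: _date = _date(2018, 2, 1)  # deployment midnight, UTC
    pre_departure_days: int = 26
    outward_days: float | None = None  # None => great-circle distance / travel_speed
    residency_days: int = 189
    inward_days: float | None = 7.0
    post_return_days: int = 20
    destination_lat: float = -64.0
    destination_lon: float = 40.0
    travel_speed_kmday: float = 170.0
    residency_dispersion_km: float = 60.0
    moult_offset_days: float = 35.0  # departure -> moult peak (window midpoint)
    moult_duration_days: float = 25.0
    light_noise_sd: float = 0.05
    shading_prob: float = 0.02
    immersion_bin_minutes: int = 240  # 240 (4 h) or 10
    temperature: bool = True
    burrow_temp_offset_c: float = 8.0
    sea_temp_base_c: float = 26.0  # at latitude 0
    sea_temp_slope_c_per_deg: float = 0.4
    sea_temp_noise_sd: float = 0.3
    isoscape: Isoscape = field(default_factory=Isoscape)
    n_body_feathers: int = 4
    feather_growth_mean_days: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        durations = [self.pre_departure_days, self.residency_days, self.post_return_days]
        durations += [d for d in (self.outward_days, self.inward_days) if d is not None]
        if any(d < 0 for d in durations):
            raise ValueError("phase durations must be >= 0")
        if self.travel_speed_kmday <= 0:
            raise ValueError("travel_speed must be > 0")
        if self.n_body_feathers < 1:
            raise ValueError("n_body_feathers must be >= 1")
        if self.immersion_bin_minutes not in (10, 240):
            raise ValueError("immersion_bin_minutes must be 10 or 240")

    @property
    def colony(self):
        return (self.colony_lat, self.colony_lon)


def _slerp(lat1, lon1, lat2, lon2, f):
    """Great-circle interpolation; f in [0, 1] (array ok)."""
    rad = np.deg2rad
    p1 = np.array([np.cos(rad(lat1)) * np.cos(rad(lon1)), np.cos(rad(lat1)) * np.sin(rad(lon1)), np.sin(rad(lat1))])
    p2 = np.array([np.cos(rad(lat2)) * np.cos(rad(lon2)), np.cos(rad(lat2)) * np.sin(rad(lon2)), np.sin(rad(lat2))])
    omega = np.arccos(np.clip(np.dot(p1, p2), -1.0, 1.0))
    f = np.asarray(f, float)
    if omega < 1e-12:
        v = np.outer(np.ones_like(f), p1)
    else:
        v = (np.outer(np.sin((1 - f) * omega), p1) + np.outer(np.sin(f * omega), p2)) / np.sin(omega)
    lat = np.rad2deg(np.arcsin(np.clip(v[:, 2], -1, 1)))
    lon = np.rad2deg(np.arctan2(v[:, 1], v[:, 0]))
    return lat, lon


@dataclass
class TrueItinerary:
    """1-min resolution ground truth for one simulated bird."""

    times: np.ndarray  # datetime64[m]
    lat: np.ndarray
    lon: np.ndarray
    state: np.ndarray  # uint8 codes, see STATE_NAMES
    config: SimConfig
    truth: dict  # scalar ground truths

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "lat": self.lat,
                "lon": self.lon,
                "state": pd.Categorical.from_codes(self.state, [STATE_NAMES[i] for i in range(4)]),
            }
        )

    def position_at(self, when) -> tuple[float, float]:
        """True (lat, lon) at the minute nearest ``when``."""
        t = np.datetime64(pd.Timestamp(when), "m")
        i = int(np.clip((t - self.times[0]) / np.timedelta64(1, "m"), 0, len(self.times) - 1))
        return float(self.lat[i]), float(self.lon[i])


def _attendance_windows(dates, cfg: SimConfig):
    """(flight_start, burrow_start, burrow_end) per attendance date.

    The bird stays on the water through dusk, flies in well after dark
    (75 min past sunset the sun is below the light sensor's dark floor, so
    colony twilights stay clean for calibration), spends up to 10 h in the
    burrow and leaves 75 min before the next sunrise.
    """
    win = []
    for d in dates:
        ss = solar.sunrise_sunset(d, cfg.colony_lon, cfg.colony_lat, altitude=0.0)[1]
        sr_next = solar.sunrise_sunset(d + pd.Timedelta(days=1), cfg.colony_lon, cfg.colony_lat, altitude=0.0)[0]
        if ss is None or sr_next is None:  # no sunset/sunrise: fixed local-night fallback
            midnight_local_utc = pd.Timestamp(d) + pd.Timedelta(hours=24.0 - cfg.colony_lon / 15.0)
            ss = midnight_local_utc - pd.Timedelta(hours=5)
            sr_next = midnight_local_utc + pd.Timedelta(hours=5)
        b_start = ss + pd.Timedelta(minutes=75)
        b_end = min(b_start + pd.Timedelta(hours=10), sr_next - pd.Timedelta(minutes=75))
        win.append((b_start - pd.Timedelta(minutes=30), b_start, b_end))
    return win


def simulate_itinerary(config: SimConfig, seed: int | None = None) -> TrueItinerary:
    """Generate the ground-truth minute-level itinerary for one bird."""
    config.validate()
    rng = np.random.default_rng([1, config.seed if seed is None else seed])

    leg_km = great_circle_km(config.colony_lat, config.colony_lon, config.destination_lat, config.destination_lon)
    out_d = config.outward_days if config.outward_days is not None else leg_km / config.travel_speed_kmday
    in_d = config.inward_days if config.inward_days is not None else leg_km / config.travel_speed_kmday
    migrates = leg_km > 1e-9 and (out_d > 0 or leg_km == 0)

    pre = float(config.pre_departure_days)
    res = float(config.residency_days)
    post = float(config.post_return_days)
    t_dep = pre
    t_res0 = pre + out_d
    t_res1 = t_res0 + res
    t_arr = t_res1 + in_d
    total_days = int(np.ceil(t_arr + post))
    if total_days <= 0:
        raise ValueError("empty season")

    n_min = total_days * 1440
    t0 = np.datetime64(pd.Timestamp(config.season_start), "m")
    times = t0 + np.arange(n_min, dtype="int64") * np.timedelta64(1, "m")
    tdays = np.arange(n_min, dtype=float) / 1440.0  # elapsed days

    lat = np.full(n_min, config.colony_lat)
    lon = np.full(n_min, config.colony_lon)

    if migrates:
        # outward great-circle leg
        m = (tdays >= t_dep) & (tdays < t_res0)
        if m.any():
            f = (tdays[m] - t_dep) / max(out_d, 1e-9)
            lat[m], lon[m] = _slerp(config.colony_lat, config.colony_lon,
                                    config.destination_lat, config.destination_lon, f)
        # residency: daily waypoints anchored on the destination
        n_way = int(np.ceil(res)) + 1
        sigma_deg_lat = config.residency_dispersion_km / 111.195
        way_lat = np.full(n_way + 1, config.destination_lat)
        way_lon = np.full(n_way + 1, config.destination_lon)
        if config.residency_dispersion_km > 0:
            off = rng.normal(0.0, config.residency_dispersion_km, size=(n_way - 1, 2))
            way_lat[1:n_way] = config.destination_lat + off[:, 1] / 111.195
            way_lon[1:n_way] = config.destination_lon + off[:, 0] / (
                111.195 * np.cos(np.deg2rad(config.destination_lat))
            )
            # keep daily steps within the travel speed (continuity invariant)
            for i in range(1, n_way):
                step = great_circle_km(way_lat[i - 1], way_lon[i - 1], way_lat[i], way_lon[i])
                if step > config.travel_speed_kmday:
                    f = config.travel_speed_kmday / step
                    way_lat[i] = way_lat[i - 1] + f * (way_lat[i] - way_lat[i - 1])
                    way_lon[i] = way_lon[i - 1] + f * (way_lon[i] - way_lon[i - 1])
        way_lat[n_way] = way_lat[n_way - 1]
        way_lon[n_way] = way_lon[n_way - 1]
        m = (tdays >= t_res0) & (tdays < t_res1)
        if m.any():
            f = tdays[m] - t_res0
            i = np.minimum(f.astype(int), n_way - 1)
            frac = f - i
            lat[m] = way_lat[i] * (1 - frac) + way_lat[i + 1] * frac
            lon[m] = way_lon[i] * (1 - frac) + way_lon[i + 1] * frac
        # inward leg from the last residency position back to the colony
        last_lat, last_lon = way_lat[min(int(res), n_way - 1)], way_lon[min(int(res), n_way - 1)]
        m = (tdays >= t_res1) & (tdays < t_arr)
        if m.any():
            f = (tdays[m] - t_res1) / max(in_d, 1e-9)
            lat[m], lon[m] = _slerp(last_lat, last_lon, config.colony_lat, config.colony_lon, f)

    # ---- behaviour states -------------------------------------------------
    state = np.full(n_min, ON_WATER, dtype=np.uint8)
    minute_of_day = np.arange(n_min) % 1440

    travel = ((tdays >= t_dep) & (tdays < t_res0)) | ((tdays >= t_res1) & (tdays < t_arr))
    state[travel & (minute_of_day % 60 < 25)] = FLIGHT

    residency = (tdays >= t_res0) & (tdays < t_res1)
    state[residency & (minute_of_day % 60 < 10)] = FLIGHT

    dep_date = pd.Timestamp(times[int(t_dep * 1440)].astype("datetime64[D]").astype("datetime64[s]"))
    moult_mid = dep_date + pd.Timedelta(days=config.moult_offset_days)
    # realized moult block: whole days centred on the peak date, so the
    # ground-truth peak equals the block's weighted centre exactly
    n_moult_days = int(round(config.moult_duration_days))
    moult_start = moult_mid - pd.Timedelta(days=(n_moult_days - 1) // 2)
    moult_end = moult_start + pd.Timedelta(days=n_moult_days)
    dates = times.astype("datetime64[D]")
    in_moult = (dates >= np.datetime64(moult_start.date())) & (dates < np.datetime64(moult_end.date())) & residency
    if config.moult_duration_days > 0:
        state[in_moult] = MOULT_ON_WATER
        # 3 x 20 min flight bouts/day (60 min: daily wet fraction 1380/1440),
        # placed so alternate 4-h bins stay fully wet
        state[in_moult & (minute_of_day % 480 < 20)] = FLIGHT

    # attendance (nightly burrow) on pre-departure and post-return dates
    att_dates = [pd.Timestamp(config.season_start) + pd.Timedelta(days=i) for i in range(int(pre))]
    first_post_day = int(np.ceil(t_arr))
    att_dates += [pd.Timestamp(config.season_start) + pd.Timedelta(days=i) for i in range(first_post_day, total_days)]
    in_colony = (tdays < t_dep) | (tdays >= t_arr)
    for ss, b0, b1 in _attendance_windows(att_dates, config):
        i_f0 = int(max((np.datetime64(ss, "m") - t0) / np.timedelta64(1, "m"), 0))
        i_b0 = int(max((np.datetime64(b0, "m") - t0) / np.timedelta64(1, "m"), 0))
        i_b1 = int(min((np.datetime64(b1, "m") - t0) / np.timedelta64(1, "m"), n_min))
        i_f1 = int(min(i_b1 + 30, n_min))
        if i_b0 >= i_b1:
            continue
        sl = slice(i_f0, i_b0)
        state[sl] = np.where(in_colony[sl], FLIGHT, state[sl])
        sl = slice(i_b0, i_b1)
        state[sl] = np.where(in_colony[sl], BURROW, state[sl])
        sl = slice(i_b1, i_f1)
        state[sl] = np.where(in_colony[sl], FLIGHT, state[sl])

    # ---- ground-truth scalars --------------------------------------------
    burrow_idx = np.flatnonzero(state == BURROW)
    dep_idx = int(t_dep * 1440)
    arr_idx = min(int(t_arr * 1440), n_min - 1)
    pre_burrow = burrow_idx[burrow_idx < dep_idx]
    post_burrow = burrow_idx[burrow_idx >= arr_idx]

    step = 10  # truth path subsampling for range (minutes)
    d_colony = great_circle_km(config.colony_lat, config.colony_lon, lat[::step], lon[::step])
    # twice-daily samples of the true path between departure and return
    half_day_idx = np.arange(dep_idx, arr_idx + 1, 720)
    seg = great_circle_km(lat[half_day_idx[:-1]], lon[half_day_idx[:-1]],
                          lat[half_day_idx[1:]], lon[half_day_idx[1:]]) if len(half_day_idx) > 1 else np.array([0.0])

    res_mask = residency if migrates else np.zeros(n_min, bool)
    if res_mask.any():
        c_lat = float(lat[res_mask].mean())
        rad = np.deg2rad(lon[res_mask])
        c_lon = float(np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))
    else:
        c_lat, c_lon = config.colony_lat, config.colony_lon

    def _d(idx_arr, which):
        if len(idx_arr) == 0:
            return None
        i = idx_arr[-1] if which == "last" else idx_arr[0]
        return pd.Timestamp(times[i].astype("datetime64[D]").astype("datetime64[s]"))

    truth = {
        "departure_date": pd.Timestamp(times[dep_idx].astype("datetime64[D]").astype("datetime64[s]")) if migrates else None,
        "return_date": pd.Timestamp(times[arr_idx].astype("datetime64[D]").astype("datetime64[s]")) if migrates else None,
        "last_attendance": _d(pre_burrow, "last"),
        "first_attendance": _d(post_burrow, "first"),
        "moult_peak_date": moult_mid if (migrates and config.moult_duration_days > 0) else None,
        "moult_start": moult_start if migrates else None,
        "moult_end": moult_end if migrates else None,
        "max_range_km": float(d_colony.max()),
        "total_distance_km": float(seg.sum()),
        "core_centroid_lat": c_lat,
        "core_centroid_lon": c_lon,
        "outward_days": float(out_d) if migrates else 0.0,
        "inward_days": float(in_d) if migrates else 0.0,
    }
    return TrueItinerary(times=times, lat=lat, lon=lon, state=state, config=config, truth=truth)


# ---- sensor rendering -----------------------------------------------------

def render_light(itin: TrueItinerary, config: SimConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Max-per-5-min light series from the itinerary.

    Columns: ``bin_start`` (UTC), ``max_light``.
    """
    cfg = config or itin.config
    rng = np.random.default_rng([2, cfg.seed if seed is None else seed])
    alt = solar.solar_altitude(itin.times, itin.lon, itin.lat)
    light = light_transfer(alt)
    light[itin.state == BURROW] = LIGHT_DARK
    if cfg.light_noise_sd > 0:
        light = light * np.exp(rng.normal(0.0, cfg.light_noise_sd, light.size))
    light = np.maximum(light, LIGHT_DARK)
    n_bins = light.size // 5
    rec = light[: n_bins * 5].reshape(n_bins, 5).max(axis=1)
    if cfg.shading_prob > 0:
        rec[rng.random(n_bins) < cfg.shading_prob] = LIGHT_DARK
    bin_start = itin.times[::5][:n_bins]
    return pd.DataFrame({"bin_start": bin_start.astype("datetime64[s]"), "max_light": rec})


def render_immersion(itin: TrueItinerary, config: SimConfig | None = None) -> pd.DataFrame:
    """Wet-sample counts per bin (30-s sampling: 2 samples per minute).

    Columns: ``bin_start``, ``n_wet``, ``n_total``, ``max_conductivity``
    (conductivity is a constant placeholder, not a measurement).
    """
    cfg = config or itin.config
    bm = cfg.immersion_bin_minutes
    wet = np.isin(itin.state, (ON_WATER, MOULT_ON_WATER))
    n_bins = wet.size // bm
    n_wet = wet[: n_bins * bm].reshape(n_bins, bm).sum(axis=1) * 2
    return pd.DataFrame(
        {
            "bin_start": itin.times[::bm][:n_bins].astype("datetime64[s]"),
            "n_wet": n_wet.astype(int),
            "n_total": np.full(n_bins, bm * 2, dtype=int),
            "max_conductivity": np.where(n_wet > 0, 127, 0),
        }
    )


def render_temperature(itin: TrueItinerary, config: SimConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Max-per-4-h temperature series (5-min sampling); empty when absent."""
    cfg = config or itin.config
    if not cfg.temperature:
        return pd.DataFrame({"bin_start": pd.Series(dtype="datetime64[s]"), "max_temp": pd.Series(dtype=float)})
    rng = np.random.default_rng([3, cfg.seed if seed is None else seed])
    idx = np.arange(0, itin.times.size, 5)
    sea = cfg.sea_temp_base_c + cfg.sea_temp_slope_c_per_deg * itin.lat[idx]
    temp = sea + rng.normal(0.0, cfg.sea_temp_noise_sd, idx.size)
    in_burrow = itin.state[idx] == BURROW
    colony_sea = cfg.sea_temp_base_c + cfg.sea_temp_slope_c_per_deg * cfg.colony_lat
    temp[in_burrow] = colony_sea + cfg.burrow_temp_offset_c
    per_bin = 48  # 4 h of 5-min samples
    n_bins = temp.size // per_bin
    rec = temp[: n_bins * per_bin].reshape(n_bins, per_bin).max(axis=1)
    return pd.DataFrame({"bin_start": itin.times[::240][:n_bins].astype("datetime64[s]"), "max_temp": rec})


def render_feathers(itin: TrueItinerary, config: SimConfig | None = None, seed: int | None = None,
                    bird_id: str = "bird0") -> pd.DataFrame:
    """Body-feather isotope values grown along the true itinerary.

    Grow dates follow a truncated exponential (mean ``feather_growth_mean_days``)
    over the post-breeding period, concentrating moult in its first months
    while leaving a tail; each feather's delta values come from the latitude
    isoscape at the bird's true position on its grow date.
    """
    cfg = config or itin.config
    rng = np.random.default_rng([4, cfg.seed if seed is None else seed])
    last = itin.truth["last_attendance"] or pd.Timestamp(itin.times[0].astype("datetime64[s]"))
    first = itin.truth["first_attendance"] or pd.Timestamp(itin.times[-1].astype("datetime64[s]"))
    span = max((first - last).total_seconds() / 86400.0, 1e-6)
    mu = cfg.feather_growth_mean_days
    u = rng.random(cfg.n_body_feathers)
    offs = -mu * np.log1p(-u * (1.0 - np.exp(-span / mu)))  # truncated exponential on [0, span]
    rows = []
    iso = cfg.isoscape
    for k, off in enumerate(np.sort(offs)):
        when = last + pd.Timedelta(days=float(off)) + pd.Timedelta(hours=12)
        glat, glon = itin.position_at(when)
        d13c = float(iso.d13c_mean(glat) + rng.normal(0.0, iso.d13c_sd))
        d15n = float(iso.d15n_mean(glat) + rng.normal(0.0, iso.d15n_sd))
        rows.append((bird_id, k, when.normalize(), glat, glon, d13c, d15n))
    return pd.DataFrame(rows, columns=["bird_id", "feather_idx", "grown_date", "grow_lat", "grow_lon", "d13C", "d15N"])


@dataclass
class SimBird:
    """One simulated bird: ground truth plus all rendered sensor streams."""

    itinerary: TrueItinerary
    light: pd.DataFrame
    immersion: pd.DataFrame
    temperature: pd.DataFrame
    feathers: pd.DataFrame
    bird_id: str = "bird0"

    @property
    def config(self) -> SimConfig:
        return self.itinerary.config

    @property
    def truth(self) -> dict:
        return self.itinerary.truth


def simulate_bird(config: SimConfig, bird_id: str = "bird0") -> SimBird:
    """Simulate one bird end to end (deterministic in (config, config.seed))."""
    itin = simulate_itinerary(config)
    return SimBird(
        itinerary=itin,
        light=render_light(itin),
        immersion=render_immersion(itin),
        temperature=render_temperature(itin),
        feathers=render_feathers(itin, bird_id=bird_id),
        bird_id=bird_id,
    )


def cohort_configs(base: SimConfig, n: int, seed: int = 0,
                   dest_lat_range: tuple[float, float] | None = None,
                   start_jitter_days: int = 0) -> list[SimConfig]:
    """Configs for a cohort: per-bird seeds plus optional between-bird variation.

    ``dest_lat_range`` draws each bird's destination latitude uniformly in the
    given interval (staggering moult habitat); ``start_jitter_days`` staggers
    season starts uniformly in +/- that many days (staggering departures).
    """
    rng = np.random.default_rng([5, seed])
    out = []
    for i in range(n):
        cfg = replace(base, seed=seed * 1000 + i)
        if dest_lat_range is not None:
            cfg = replace(cfg, destination_lat=float(rng.uniform(*dest_lat_range)))
        if start_jitter_days:
            shift = int(rng.integers(-start_jitter_days, start_jitter_days + 1))
            cfg = replace(cfg, season_start=(pd.Timestamp(base.season_start) + pd.Timedelta(days=shift)).date())
        out.append(cfg)
    return out
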