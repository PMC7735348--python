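"""Behavioural phenology from immersion and temperature streams.

Daily activity budgets (fraction of 30-s wet/dry samples wet per UTC day),
wing-moult detection (the flightless period shows as a block of days more
than 90% wet), burrow-attendance detection (a fully dry bout longer than
4 h, corroborated by elevated logger temperature and/or position estimates
near the colony), and assembly of the per-bird migration summary:
last/first burrow occupancy, departure and return dates, outward/inward
travel durations, migration duration, maximum range, total distance, mean
wing-moult date and the departure-to-moult interval.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import track as trackmod

__all__ = [
    "daily_wet_fraction",
    "MoultWindow",
    "detect_moult",
    "detect_attendance",
    "MigrationSummary",
    "migration_summary",
    "movement_window",
]


def daily_wet_fraction(immersion: pd.DataFrame) -> pd.DataFrame:
    """Daily activity from binned wet-sample counts.

    Returns a date-indexed frame with ``wet_fraction`` (exact ratio of wet
    to total samples), ``n_samples``, ``longest_dry_bout_h`` (from runs of
    fully dry bins within the day, so it is resolved no finer than the bin
    width) and ``partial`` (True when the day holds under 75% of a full
    day's samples).
    """
    if len(immersion) == 0:
        raise ValueError("empty immersion stream")
    imm = immersion.copy()
    t = pd.DatetimeIndex(imm["bin_start"])
    imm["date"] = t.normalize()
    bin_minutes = (imm["n_total"].iloc[0] / 2.0)
    rows = []
    for d, g in imm.groupby("date"):
        n_tot = int(g["n_total"].sum())
        wf = float(g["n_wet"].sum()) / n_tot
        dry = (g["n_wet"].to_numpy() == 0).astype(int)
        longest = run = 0
        for x in dry:
            run = run + x if x else 0
            longest = max(longest, run)
        rows.append((d, wf, n_tot, min(longest * bin_minutes / 60.0, 24.0), n_tot < 0.75 * 2880))
    out = pd.DataFrame(rows, columns=["date", "wet_fraction", "n_samples", "longest_dry_bout_h", "partial"])
    return out.set_index("date")


@dataclass(frozen=True)
class MoultWindow:
    start: pd.Timestamp
    end: pd.Timestamp
    peak_date: pd.Timestamp  # the "mean wing moult date"
    mean_wet_fraction: float
    n_days: int


def detect_moult(activity: pd.DataFrame, threshold: float = 0.9, smooth_days: int = 5) -> MoultWindow | None:
    """Wing-moult window: the longest run of days wetter than ``threshold``.

    The daily wet fraction is smoothed with a centred ``smooth_days`` rolling
    mean before thresholding (suppressing single-day dropouts; pass
    ``smooth_days=1`` for the raw-day rule).  The peak date — the mean
    wing-moult date — is the density-weighted centre of the run, with
    weights (smoothed wet fraction - threshold).  Returns None when no day
    exceeds the threshold.
    """
    if len(activity) < 30:
        raise ValueError("need >= 30 days of activity")
    wf = activity["wet_fraction"].rolling(smooth_days, center=True, min_periods=1).mean()
    above = (wf > threshold).to_numpy()
    if not above.any():
        return None
    # longest run of consecutive above-threshold days (first wins ties)
    best_len, best_start, run, start = 0, 0, 0, 0
    for i, b in enumerate(above):
        if b:
            if run == 0:
                start = i
            run += 1
            if run > best_len:
                best_len, best_start = run, start
        else:
            run = 0
    sl = slice(best_start, best_start + best_len)
    dates = activity.index[sl]
    w = (wf.iloc[sl] - threshold).to_numpy()
    w = np.maximum(w, 0.0)
    days = (dates - dates[0]).days.to_numpy(float)
    center = float(np.sum(w * days) / np.sum(w)) if w.sum() > 0 else days.mean()
    peak = dates[0] + pd.Timedelta(days=round(center))
    return MoultWindow(
        start=dates[0],
        end=dates[-1],
        peak_date=peak,
        mean_wet_fraction=float(activity["wet_fraction"].iloc[sl].mean()),
        n_days=int(best_len),
    )


def detect_attendance(immersion: pd.DataFrame, temperature: pd.DataFrame | None = None,
                      positions: pd.DataFrame | None = None, colony=None,
                      delta_t_c: float = 5.0, r_prox_km: float = 500.0,
                      min_dry_h: float = 4.0) -> pd.DataFrame:
    """Burrow-attendance events: fully dry bouts longer than ``min_dry_h``.

    A candidate is a maximal run of fully dry bins.  The true dry bout
    extends into the partially wet bins at each end, so the run qualifies
    when its span plus one bin width exceeds ``min_dry_h`` — with 4-h bins
    a single fully dry bin qualifies (the rule cannot be applied more
    strictly than the bin resolution), while with 10-min bins the span
    itself must effectively exceed 4 h.
    When a temperature stream exists the bout must contain a bin at least
    ``delta_t_c`` above the rolling 10-day sea baseline (the baseline is the
    rolling median of each day's coolest bin, which is robust to the warm
    burrow bins themselves); when positions exist the nearest fix within a
    day must lie within ``r_prox_km`` of the colony.  With neither stream
    the candidate is accepted with both corroboration flags False.

    Returns a frame with ``date`` (bout start date), ``start``, ``end``,
    ``dry_bout_h``, ``temperature_corroborated``, ``proximity_corroborated``,
    ``accepted``.
    """
    imm = immersion.sort_values("bin_start").reset_index(drop=True)
    bin_h = imm["n_total"].iloc[0] / 2.0 / 60.0
    dry = imm["n_wet"].to_numpy() == 0
    t = pd.DatetimeIndex(imm["bin_start"])

    have_temp = temperature is not None and len(temperature) > 0
    if have_temp:
        tmp = temperature.sort_values("bin_start")
        tt = pd.DatetimeIndex(tmp["bin_start"])
        daily_min = tmp.assign(date=tt.normalize()).groupby("date")["max_temp"].min()
        baseline = daily_min.rolling(10, center=True, min_periods=1).median()
    have_pos = positions is not None and len(positions) > 0 and colony is not None
    if have_pos:
        pos = positions.sort_values("time")  # keep latitude-less (equinox) fixes
        pos_t = pd.DatetimeIndex(pos["time"])

    rows = []
    i = 0
    n = len(imm)
    while i < n:
        if not dry[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and dry[j + 1]:
            j += 1
        bout_h = (j - i + 1) * bin_h
        start, end = t[i], t[j] + pd.Timedelta(hours=bin_h)
        if bout_h + bin_h > min_dry_h:
            temp_ok = False
            if have_temp:
                sel = tmp[(tt >= start - pd.Timedelta(hours=4)) & (tt < end)]
                if len(sel):
                    base = baseline.reindex(pd.DatetimeIndex(sel["bin_start"]).normalize()).to_numpy()
                    temp_ok = bool(np.any(sel["max_temp"].to_numpy() >= base + delta_t_c))
            prox_ok = False
            if have_pos and len(pos):
                k = int(np.argmin(np.abs((pos_t - start).total_seconds())))
                if abs((pos_t[k] - start).total_seconds()) <= 86400:
                    plat, plon = pos["lat"].iloc[k], pos["lon"].iloc[k]
                    if np.isfinite(plat):
                        d = trackmod.great_circle_km(colony[0], colony[1], plat, plon)
                    else:  # equinox fix: longitude-only distance along the colony parallel
                        d = trackmod.great_circle_km(colony[0], colony[1], colony[0], plon)
                    prox_ok = bool(d <= r_prox_km)
            accepted = (temp_ok or not have_temp) and (prox_ok or not have_pos)
            rows.append((start.normalize(), start, end, bout_h, temp_ok, prox_ok, accepted))
        i = j + 1
    return pd.DataFrame(
        rows,
        columns=["date", "start", "end", "dry_bout_h", "temperature_corroborated",
                 "proximity_corroborated", "accepted"],
    )


@dataclass
class MigrationSummary:
    """The per-bird migration metric set."""

    last_burrow_occupancy: pd.Timestamp | None = None
    departure_date: pd.Timestamp | None = None
    outward_travel_days: float | None = None
    migration_duration_days: float | None = None
    inward_travel_days: float | None = None
    return_date: pd.Timestamp | None = None
    first_burrow_occupancy: pd.Timestamp | None = None
    max_range_km: float | None = None
    max_range_smoothed_km: float | None = None
    total_distance_km: float | None = None
    total_distance_smoothed_km: float | None = None
    mean_wing_moult_date: pd.Timestamp | None = None
    departure_to_moult_days: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def movement_window(track: pd.DataFrame, colony, daily_lon: pd.Series | None = None,
                    far_km: float = 200.0, persistence_days: int = 2,
                    min_shift_deg: float = 5.0) -> tuple[pd.Timestamp | None, pd.Timestamp | None]:
    """(departure, return) dates of the sustained away-from-colony period.

    The primary rule thresholds the colony distance of 3-day rolling-mean
    daily positions at ``far_km`` (sustained for ``persistence_days``): the
    longest far run gives departure = its first day and return = the day
    after its last day.  When either end abuts an equinox window (where
    latitudes, hence distances, are missing) that end falls back to the
    longitudinal change-point onset on the raw daily longitudes.
    """
    kept = trackmod.usable_fixes(track)
    dep = ret = None
    if len(kept) >= 4:
        tt = pd.DatetimeIndex(kept["time"]).normalize()
        daily = kept.assign(date=tt).groupby("date")[["lat", "lon"]].mean()
        # date-aware smoothing: a 3-calendar-day window, so days across an
        # equinox gap do not contaminate each other
        full = daily.reindex(pd.date_range(daily.index[0], daily.index[-1], freq="D"))
        lat_s = full["lat"].rolling(3, center=True, min_periods=1).mean().reindex(daily.index)
        lon_s = full["lon"].rolling(3, center=True, min_periods=1).mean().reindex(daily.index)
        dist = trackmod.great_circle_km(colony[0], colony[1], lat_s.to_numpy(), lon_s.to_numpy())
        far = dist > far_km
        best_len, best_start, run, start = 0, 0, 0, 0
        for i, b in enumerate(far):
            if b:
                if run == 0:
                    start = i
                run += 1
                if run > best_len:
                    best_len, best_start = run, start
            else:
                run = 0
        if best_len >= persistence_days:
            dep = daily.index[best_start]
            last_far = daily.index[best_start + best_len - 1]
            ret = last_far + pd.Timedelta(days=1)
            # an end adjoining a gap in the daily positions (latitudes missing
            # around an equinox) is unreliable: fall back to longitude timing
            if best_start == 0 or (dep - daily.index[best_start - 1]).days > 2:
                dep = None
            if best_start + best_len < len(daily.index):
                if (daily.index[best_start + best_len] - last_far).days > 2:
                    ret = None
            elif trackmod.in_equinox_window([last_far + pd.Timedelta(days=1)]).any():
                ret = None
    if daily_lon is not None:
        if dep is None:
            cp = trackmod.longitudinal_changepoint(daily_lon, colony[1], min_shift_deg, 3)
            dep = cp.onset if cp else None
        if ret is None:
            cp = trackmod.longitudinal_changepoint(daily_lon, colony[1], min_shift_deg, 3, reverse=True)
            ret = cp.onset if cp else None
    return dep, ret


def migration_summary(activity: pd.DataFrame, moult: MoultWindow | None,
                      attendance: pd.DataFrame, track: pd.DataFrame, colony,
                      daily_lon: pd.Series | None = None, core_contour=None) -> MigrationSummary:
    """Assemble the per-bird migration metric set.

    Last/first burrow occupancy bracket the longest gap between accepted
    attendance events; departure/return come from :func:`movement_window`;
    outward (inward) travel duration runs from departure (to return) until
    (from) the first (last) kept fix inside the 50% UD core; distance
    metrics are computed over [departure, return].  Missing inputs null the
    corresponding fields without failing the rest.
    """
    summary = MigrationSummary()

    acc = attendance[attendance["accepted"]] if len(attendance) else attendance
    if len(acc) >= 2:
        dates = pd.DatetimeIndex(acc["date"]).unique().sort_values()
        gaps = (dates[1:] - dates[:-1]).days
        k = int(np.argmax(gaps))
        summary.last_burrow_occupancy = dates[k]
        summary.first_burrow_occupancy = dates[k + 1]
    elif len(acc) == 1:
        summary.last_burrow_occupancy = pd.Timestamp(acc["date"].iloc[0])

    dep, ret = movement_window(track, colony, daily_lon=daily_lon)
    # attendance is direct evidence of colony presence: movement-based
    # departure/return cannot precede the last / follow the first burrow visit
    if dep is not None and summary.last_burrow_occupancy is not None and dep < summary.last_burrow_occupancy:
        dep = summary.last_burrow_occupancy
    if ret is not None and summary.first_burrow_occupancy is not None and ret > summary.first_burrow_occupancy:
        ret = summary.first_burrow_occupancy
    if dep is not None and ret is not None and dep > ret:
        ret = None
    summary.departure_date = dep
    summary.return_date = ret
    if dep is not None and ret is not None:
        summary.migration_duration_days = float((ret - dep).days)
        try:
            metrics = trackmod.track_metrics(track, colony, window=(dep, ret))
            summary.max_range_km = metrics["max_range_km"]
            summary.max_range_smoothed_km = metrics["max_range_smoothed_km"]
            summary.total_distance_km = metrics["total_distance_km"]
            summary.total_distance_smoothed_km = metrics["total_distance_smoothed_km"]
        except ValueError:
            pass

    if moult is not None:
        summary.mean_wing_moult_date = moult.peak_date
        if dep is not None:
            summary.departure_to_moult_days = float((moult.peak_date - dep).days)

    if core_contour is not None and dep is not None and ret is not None:
        kept = trackmod.usable_fixes(track).copy()
        tt = pd.DatetimeIndex(kept["time"])
        kept = kept[(tt >= dep) & (tt <= ret)]
        if len(kept):
            from shapely.geometry import Point

            poly = core_contour.polygon.buffer(1e-9)
            in_core = [poly.contains(Point(r.lon, r.lat)) for r in kept.itertuples()]
            kt = pd.DatetimeIndex(kept["time"])[np.asarray(in_core, bool)]
            if len(kt):
                summary.outward_travel_days = float((kt[0].normalize() - dep).days)
                summary.inward_travel_days = float((ret - kt[-1].normalize()).days)
    return summary
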