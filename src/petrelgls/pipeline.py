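"""End-to-end analysis of one bird's geolocator record.

Chains the full post-breeding workflow: twilight detection, in-habitat
calibration, twice-daily position estimation, equinox and speed filtering,
kernel home ranges, activity/moult/attendance phenology and the migration
summary.  This is the composition the per-module functions are designed
for; each stage can equally be run on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geolocate, phenology, spaceuse, track as trackmod
from .simulate import DEFAULT_LIGHT_THRESHOLD, SimBird

__all__ = ["BirdAnalysis", "analyze_bird", "analyze_sim_bird"]


@dataclass
class BirdAnalysis:
    calibration: geolocate.Calibration
    positions: pd.DataFrame  # raw twice-daily estimates
    track: pd.DataFrame  # flagged/filtered positions
    daily_lon: pd.Series  # raw daily median longitude (equinox days included)
    activity: pd.DataFrame
    moult: phenology.MoultWindow | None
    attendance: pd.DataFrame
    ud: spaceuse.KernelUD | None
    core: spaceuse.UDContour | None  # 50% contour
    home_range: spaceuse.UDContour | None  # 95% contour
    centroid: tuple | None  # (lat, lon) of the core centroid
    summary: phenology.MigrationSummary


def analyze_bird(light: pd.DataFrame, immersion: pd.DataFrame, colony,
                 temperature: pd.DataFrame | None = None,
                 light_threshold: float = DEFAULT_LIGHT_THRESHOLD,
                 calibration_days: int = 20,
                 h: float = 1.8, grid: float = 1.0) -> BirdAnalysis:
    """Run the full pipeline on one bird's sensor streams.

    ``colony`` is the known (lat, lon) deployment site; the first
    ``calibration_days`` of the light record (while the bird attends the
    colony) serve as the calibration window.
    """
    t0 = pd.Timestamp(light["bin_start"].iloc[0])
    cal = geolocate.calibrate_sun_altitude(
        light, colony, (t0, t0 + pd.Timedelta(days=calibration_days)), light_threshold
    )
    twilights = geolocate.detect_twilights(light, light_threshold)
    positions = geolocate.estimate_positions(twilights, cal)

    flagged = trackmod.flag_equinox(positions)
    filtered = trackmod.speed_filter(flagged)
    daily_lon = positions.assign(date=pd.DatetimeIndex(positions["time"]).normalize()) \
        .groupby("date")["lon"].median()

    activity = phenology.daily_wet_fraction(immersion)
    try:
        moult = phenology.detect_moult(activity)
    except ValueError:
        moult = None
    attendance = phenology.detect_attendance(immersion, temperature, filtered, colony)

    dep, ret = phenology.movement_window(filtered, colony, daily_lon=daily_lon)
    kept = trackmod.usable_fixes(filtered)
    if dep is not None and ret is not None:
        tt = pd.DatetimeIndex(kept["time"])
        mig = kept[(tt >= dep) & (tt <= ret)]
        if len(mig) >= 2:
            kept = mig
    ud = core = home = centroid = None
    if len(kept) >= 2:
        ud = spaceuse.kernel_ud(kept["lat"].to_numpy(), kept["lon"].to_numpy(), h=h, grid=grid)
        core = spaceuse.ud_contour(ud, 50.0)
        home = spaceuse.ud_contour(ud, 95.0)
        centroid = spaceuse.core_centroid(ud)

    summary = phenology.migration_summary(activity, moult, attendance, filtered, colony,
                                          daily_lon=daily_lon, core_contour=core)
    return BirdAnalysis(
        calibration=cal,
        positions=positions,
        track=filtered,
        daily_lon=daily_lon,
        activity=activity,
        moult=moult,
        attendance=attendance,
        ud=ud,
        core=core,
        home_range=home,
        centroid=centroid,
        summary=summary,
    )


def analyze_sim_bird(bird: SimBird, **kwargs) -> BirdAnalysis:
    """Convenience: run :func:`analyze_bird` on a simulated bird."""
    cfg = bird.config
    return analyze_bird(bird.light, bird.immersion, (cfg.colony_lat, cfg.colony_lon),
                        temperature=bird.temperature if len(bird.temperature) else None, **kwargs)
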