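"""Great-circle math, equinox/speed filters, change-point, trip metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import petrelgls as pg
from petrelgls import track


def test_haversine_basic_values():
    assert track.great_circle_km(10.0, 20.0, 10.0, 20.0) == 0.0
    # half circumference: pi * 6371
    assert track.great_circle_km(0.0, 0.0, 0.0, 180.0) == pytest.approx(np.pi * 6371.0, rel=1e-9)
    # independent oracle: spherical law of cosines
    lat1, lon1, lat2, lon2 = -50.0, 70.0, -50.0, 90.0
    rad = np.deg2rad
    cos_d = (np.sin(rad(lat1)) * np.sin(rad(lat2))
             + np.cos(rad(lat1)) * np.cos(rad(lat2)) * np.cos(rad(lon2 - lon1)))
    oracle = 6371.0 * np.arccos(cos_d)
    got = track.great_circle_km(lat1, lon1, lat2, lon2)
    assert got == pytest.approx(oracle, rel=1e-9)
    # the along-parallel arc 20*111.195*cos50 = 1429.5 is within 0.4%
    assert got == pytest.approx(1429.5, rel=0.004)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.floats(-89, 89), st.floats(-180, 180), st.floats(-89, 89), st.floats(-180, 180))
def test_haversine_symmetric_and_bounded(lat1, lon1, lat2, lon2):
    d1 = track.great_circle_km(lat1, lon1, lat2, lon2)
    d2 = track.great_circle_km(lat2, lon2, lat1, lon1)
    assert d1 == pytest.approx(d2, rel=1e-12, abs=1e-9)
    assert 0.0 <= d1 <= np.pi * 6371.0 + 1e-6


def _positions(dates, lats, lons):
    return pd.DataFrame({
        "time": pd.DatetimeIndex(dates), "lat": lats, "lon": lons,
        "lat_reliable": True,
    })


def test_equinox_window_boundaries():
    pos = _positions(["2018-03-21", "2018-06-01", "2018-04-03", "2018-04-04"],
                     [-50.0] * 4, [70.0] * 4)
    out = track.flag_equinox(pos)
    flags = out["flag"].tolist()
    assert flags[0] == "equinox_excluded"  # 21 March
    assert flags[1] == "kept"  # 1 June
    assert flags[2] == "equinox_excluded"  # 14 days after the equinox
    assert flags[3] == "kept"  # 15 days after: window closed at 14
    # longitude is never dropped
    assert out["lon"].notna().all()


def test_equinox_exclusion_covers_58_days_per_year():
    days = pd.date_range("2018-01-01", "2018-12-31", freq="D")
    mask = track.in_equinox_window(days)
    assert abs(int(mask.sum()) - 58) <= 2


def test_speed_filter_drops_teleport_only():
    t = pd.date_range("2018-05-01", periods=10, freq="12h")
    lats = np.full(10, -50.0)
    lons = 70.0 + np.arange(10) * 0.5
    pos = _positions(t, lats, lons)
    pos.loc[4, "lat"] = -68.0  # ~2000 km teleport within 12 h
    out = track.speed_filter(pos)
    assert (out["flag"] == "speed_excluded").sum() == 1
    assert out.loc[4, "flag"] == "speed_excluded"
    # two fixes ~1425 km apart in one day survive (below 1500 km/d)
    slow = _positions(pd.DatetimeIndex(["2018-05-01", "2018-05-02"]), [-50, -50], [70, 90])
    assert (track.speed_filter(slow)["flag"] == "kept").all()


def test_speed_filter_single_position_unchanged():
    one = _positions(["2018-05-01"], [-50.0], [70.0])
    out = track.speed_filter(one)
    assert len(out) == 1 and out["flag"].iloc[0] == "kept"


def test_speed_filter_invariant_no_fast_pair(default_analysis):
    kept = track.usable_fixes(default_analysis.track)
    t = pd.DatetimeIndex(kept["time"])
    dt_days = np.diff(t.view("int64")) / 86400e9
    d = track.great_circle_km(kept["lat"].to_numpy()[:-1], kept["lon"].to_numpy()[:-1],
                              kept["lat"].to_numpy()[1:], kept["lon"].to_numpy()[1:])
    assert np.all(d / np.maximum(dt_days, 1e-9) <= 1500.0 + 1e-6)


def _naive_changepoint(shifts, min_shift, persistence):
    """Independent exhaustive day scan for the trigger date."""
    n = len(shifts)
    for i in range(n - persistence + 1):
        if all(shifts[i + k] > min_shift for k in range(persistence)):
            return i
    return None


def test_changepoint_constructed_drift():
    # 20 colony days then -1 deg/day drift: trigger on first |shift| > 5 day
    lons = [70.0] * 20 + [70.0 - (i + 1) for i in range(20)]
    dates = pd.date_range("2018-05-01", periods=40, freq="D")
    cp = track.longitudinal_changepoint(pd.Series(lons, index=dates), 70.0)
    assert cp.trigger == dates[25]  # first day with shift 6 > 5
    # onset back-dates to just after the last near-colony-longitude day; for
    # a slow 1 deg/day drift that is the drift start plus the half-shift band
    assert dates[20] <= cp.onset <= dates[23]
    # constant series: no changepoint
    assert track.longitudinal_changepoint(pd.Series([70.0] * 30, index=pd.date_range("2018-05-01", periods=30)), 70.0) is None


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.lists(st.floats(-30, 30), min_size=10, max_size=60), st.integers(1, 4))
def test_changepoint_equals_exhaustive_scan(shifts, persistence):
    lons = pd.Series(np.asarray(shifts) + 70.0, index=pd.date_range("2018-01-01", periods=len(shifts)))
    cp = track.longitudinal_changepoint(lons, 70.0, 5.0, persistence)
    naive = _naive_changepoint(np.abs(np.asarray(shifts)), 5.0, persistence)
    if naive is None:
        assert cp is None
    else:
        assert cp.trigger == lons.index[naive]


def test_track_metrics_out_and_back():
    # out 2500 km due south and back, no noise: total = 5000, range = 2500
    colony = (-40.0, 70.0)
    lat_out = -40.0 - np.linspace(0, 2500, 26) / 111.195
    lats = np.concatenate([lat_out, lat_out[::-1][1:]])
    t = pd.date_range("2018-05-01", periods=len(lats), freq="12h")
    trk = _positions(t, lats, np.full(len(lats), 70.0))
    trk["flag"] = "kept"
    m = track.track_metrics(trk, colony)
    assert m["max_range_km"] == pytest.approx(2500.0, rel=0.01)
    assert m["total_distance_km"] == pytest.approx(5000.0, rel=0.01)
    assert m["max_range_km"] <= m["total_distance_km"]


def test_track_metrics_jitter_inflates_raw_not_smoothed():
    rng = np.random.default_rng(0)
    colony = (-40.0, 70.0)
    lat_out = -40.0 - np.linspace(0, 2500, 26) / 111.195
    lats = np.concatenate([lat_out, lat_out[::-1][1:]])
    n = len(lats)
    t = pd.date_range("2018-05-01", periods=n, freq="12h")
    jlat = lats + rng.normal(0, 100 / 111.195, n)
    jlon = 70.0 + rng.normal(0, 100 / 111.195, n)
    m = track.track_metrics(_positions(t, jlat, jlon).assign(flag="kept"), colony)
    assert m["total_distance_km"] > m["total_distance_smoothed_km"]
    assert m["total_distance_smoothed_km"] == pytest.approx(5000.0, rel=0.15)


def test_track_metrics_needs_two_positions():
    with pytest.raises(ValueError):
        track.track_metrics(_positions(["2018-05-01"], [-50.0], [70.0]).assign(flag="kept"), (-50, 70))


def test_wrap_lon_range():
    assert track.wrap_lon(190.0) == -170.0
    assert track.wrap_lon(180.0) == 180.0
    assert track.wrap_lon(-180.0) == 180.0
    vals = track.wrap_lon(np.arange(-720, 720, 7.3))
    assert np.all((vals > -180.0) & (vals <= 180.0))
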