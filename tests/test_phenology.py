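"""Activity budgets, moult and attendance detection, migration summary."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import petrelgls as pg
from petrelgls import phenology

from conftest import compact_config, stationary_config


def _immersion(day_wets, bin_minutes=240):
    """Build an immersion frame from per-day lists of per-bin wet counts."""
    rows = []
    t = pd.Timestamp("2018-05-01")
    per_day = 1440 // bin_minutes
    for day in day_wets:
        assert len(day) == per_day
        for b, w in enumerate(day):
            rows.append((t + pd.Timedelta(minutes=b * bin_minutes), w, bin_minutes * 2))
        t += pd.Timedelta(days=1)
    df = pd.DataFrame(rows, columns=["bin_start", "n_wet", "n_total"])
    df["max_conductivity"] = np.where(df["n_wet"] > 0, 127, 0)
    return df


def test_daily_wet_fraction_arithmetic():
    act = phenology.daily_wet_fraction(_immersion([[432] * 6, [0] * 6]))
    assert act["wet_fraction"].iloc[0] == pytest.approx(0.9)  # 6 x 432/480
    assert act["wet_fraction"].iloc[1] == 0.0
    assert act["longest_dry_bout_h"].iloc[1] == 24.0
    assert (act["n_samples"] == 2880).all()
    with pytest.raises(ValueError):
        phenology.daily_wet_fraction(_immersion([]))


def test_wet_fraction_matches_minute_truth(compact_bird):
    act = phenology.daily_wet_fraction(compact_bird.immersion)
    itin = compact_bird.itinerary
    df = itin.to_dataframe()
    df["date"] = pd.DatetimeIndex(df["time"]).normalize()
    wet_truth = df.groupby("date")["state"].apply(lambda s: s.isin(["on_water", "moult_on_water"]).mean())
    joined = act.join(wet_truth.rename("truth"))
    assert np.allclose(joined["wet_fraction"], joined["truth"], atol=1e-9)


def _activity(wfs):
    dates = pd.date_range("2018-05-01", periods=len(wfs), freq="D")
    return pd.DataFrame({"wet_fraction": wfs, "n_samples": 2880,
                         "longest_dry_bout_h": 0.0, "partial": False}, index=dates)


def test_moult_peak_centered_on_symmetric_block():
    wfs = np.full(80, 0.5)
    wfs[30:50] = 0.95  # 20-day block centred on day 39.5
    m = phenology.detect_moult(_activity(wfs))
    assert m is not None
    center = pd.Timestamp("2018-05-01") + pd.Timedelta(days=39.5)
    assert abs((m.peak_date - center).days) <= 1
    assert m.start <= m.peak_date <= m.end


def test_no_moult_when_never_above_threshold():
    assert phenology.detect_moult(_activity(np.full(60, 0.85))) is None
    with pytest.raises(ValueError):
        phenology.detect_moult(_activity(np.full(10, 0.95)))


def test_moult_longest_run_wins():
    wfs = np.full(90, 0.5)
    wfs[10:18] = 0.97   # 8-day run
    wfs[40:55] = 0.97   # 15-day run: chosen
    m = phenology.detect_moult(_activity(wfs))
    base = pd.Timestamp("2018-05-01")
    assert base + pd.Timedelta(days=38) <= m.start <= base + pd.Timedelta(days=42)
    assert base + pd.Timedelta(days=52) <= m.end <= base + pd.Timedelta(days=56)
    # brute-force run scan oracle on the smoothed series
    sm = pd.Series(wfs).rolling(5, center=True, min_periods=1).mean().to_numpy()
    runs, cur = [], 0
    for i, v in enumerate(sm):
        cur = cur + 1 if v > 0.9 else 0
        runs.append((cur, i))
    best_len, best_end = max(runs)
    assert m.n_days == best_len
    assert m.end == base + pd.Timedelta(days=int(best_end))


def test_moult_invariant_to_immersion_regime(compact_bird):
    itin = compact_bird.itinerary
    cfg10 = replace(compact_bird.config, immersion_bin_minutes=10)
    act4 = phenology.daily_wet_fraction(compact_bird.immersion)
    act10 = phenology.daily_wet_fraction(pg.simulate.render_immersion(itin, cfg10))
    m4 = phenology.detect_moult(act4)
    m10 = phenology.detect_moult(act10)
    assert abs((m4.peak_date - m10.peak_date).days) <= 1


def _const_temp(n_days, base=6.0):
    t = pd.date_range("2018-05-01", periods=n_days * 6, freq="4h")
    return pd.DataFrame({"bin_start": t, "max_temp": base})


def test_attendance_rules():
    # day 0: 3-h dry bout (no event); day 1: 12-h dry bout (event)
    days = [[480, 480, 444, 480, 480, 480],  # one partially dry bin only
            [480, 480, 480, 0, 0, 0],
            [0, 480, 480, 480, 480, 480]]
    imm = _immersion(days)
    temp = _const_temp(3)
    # warm the bins of the long bout
    mask = (temp["bin_start"] >= "2018-05-02 12:00") & (temp["bin_start"] < "2018-05-03 04:00")
    temp.loc[mask, "max_temp"] = 14.0
    positions = pd.DataFrame({
        "time": [pd.Timestamp("2018-05-02 18:00")],
        "lat": [-49.0], "lon": [70.0], "lat_reliable": [True], "flag": ["kept"],
    })
    ev = phenology.detect_attendance(imm, temp, positions, colony=(-49.47, 69.95))
    assert len(ev) == 1
    e = ev.iloc[0]
    assert e["dry_bout_h"] >= 12.0
    assert e["temperature_corroborated"] and e["proximity_corroborated"] and e["accepted"]


def test_attendance_rejected_when_far_from_colony():
    days = [[480, 480, 480, 0, 0, 0], [0, 480, 480, 480, 480, 480]]
    imm = _immersion(days)
    far = pd.DataFrame({
        "time": [pd.Timestamp("2018-05-01 18:00")],
        "lat": [-49.0], "lon": [95.0], "lat_reliable": [True], "flag": ["kept"],  # ~1800 km east
    })
    ev = phenology.detect_attendance(imm, None, far, colony=(-49.47, 69.95))
    assert len(ev) == 1 and not ev["accepted"].iloc[0]
    # with neither corroborating stream the candidate is accepted, flags False
    ev2 = phenology.detect_attendance(imm, None, None, None)
    assert ev2["accepted"].iloc[0]
    assert not ev2["temperature_corroborated"].iloc[0]


def test_stationary_bird_summary_has_null_departure():
    bird = pg.simulate_bird(stationary_config(seed=2, days=40))
    res = pg.analyze_sim_bird(bird)
    s = res.summary
    assert s.departure_date is None
    assert s.migration_duration_days is None
    assert s.mean_wing_moult_date is None or s.departure_to_moult_days is None


def test_summary_ordering_and_intervals(default_bird, default_analysis):
    s = default_analysis.summary
    tr = default_bird.truth
    assert s.last_burrow_occupancy <= s.departure_date <= s.return_date <= s.first_burrow_occupancy
    assert s.migration_duration_days == (s.return_date - s.departure_date).days
    assert s.departure_to_moult_days is not None and s.departure_to_moult_days >= 0
    assert (s.outward_travel_days or 0) + (s.inward_travel_days or 0) <= s.migration_duration_days
    # recovery against simulator truth
    assert abs((s.departure_date - tr["departure_date"]).days) <= 2
    assert abs((s.return_date - tr["return_date"]).days) <= 2
    assert abs((s.mean_wing_moult_date - tr["moult_peak_date"]).days) <= 3
    assert abs(s.departure_to_moult_days - 35.0) <= 3.0


def test_departure_moult_correlation_across_staggered_cohort():
    # staggered departures, fixed moult offset: moult peak tracks departure
    base = compact_config()
    configs = pg.simulate.cohort_configs(base, 12, seed=3, start_jitter_days=12)
    deps, moults = [], []
    for cfg in configs:
        bird = pg.simulate_bird(cfg)
        res = pg.analyze_sim_bird(bird)
        s = res.summary
        if s.departure_date is None or s.mean_wing_moult_date is None:
            continue
        deps.append(s.departure_date.toordinal())
        moults.append(s.mean_wing_moult_date.toordinal())
    assert len(deps) >= 10
    rho, _ = pg.isotopes.spearman_rho(deps, moults)
    assert rho > 0.9
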