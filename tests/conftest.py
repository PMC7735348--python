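"""Shared fixtures: simulated birds reused across test modules."""

from datetime import date

import pytest

import petrelgls as pg


def compact_config(seed: int = 0, **overrides) -> pg.SimConfig:
    """A short winter season (no equinox overlap) for fast structural sweeps.

    Kerguelen-like colony, ~1000 km outward leg, 55-day residency; the moult
    block still peaks 35 days after departure.  Full pipeline runs in ~0.25 s.
    """
    kw = dict(
        season_start=date(2018, 5, 1),
        pre_departure_days=10,
        residency_days=55,
        inward_days=4.0,
        post_return_days=10,
        destination_lat=-57.0,
        destination_lon=62.0,
        seed=seed,
    )
    kw.update(overrides)
    return pg.SimConfig(**kw)


def stationary_config(seed: int = 0, *, lat=-49.47, lon=69.95,
                      start=date(2018, 4, 20), days=60, noiseless=False,
                      **overrides) -> pg.SimConfig:
    """A bird that floats at a fixed position (destination == colony)."""
    kw = dict(
        colony_lat=lat, colony_lon=lon,
        destination_lat=lat, destination_lon=lon,
        season_start=start,
        pre_departure_days=0, residency_days=days, inward_days=0.0,
        post_return_days=0, residency_dispersion_km=0.0, seed=seed,
    )
    if noiseless:
        kw.update(light_noise_sd=0.0, shading_prob=0.0)
    kw.update(overrides)
    return pg.SimConfig(**kw)


@pytest.fixture(scope="session")
def default_bird():
    return pg.simulate_bird(pg.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_bird):
    return pg.analyze_sim_bird(default_bird)


@pytest.fixture(scope="session")
def compact_bird():
    return pg.simulate_bird(compact_config(seed=0))


@pytest.fixture(scope="session")
def compact_analysis(compact_bird):
    return pg.analyze_sim_bird(compact_bird)
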