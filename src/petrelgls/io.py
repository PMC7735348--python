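"""Plain-text serialization of simulated birds and analysis inputs.

Schemas (all CSV, UTC ISO-8601 timestamps):

* ``light.csv``       — bin_start, max_light
* ``immersion.csv``   — bin_start, n_wet, n_total, max_conductivity
* ``temperature.csv`` — bin_start, max_temp
* ``feathers.csv``    — bird_id, feather_idx, grown_date, grow_lat, grow_lon, d13C, d15N
* ``truth.json``      — the simulator's scalar ground truths
* ``config.json``     — SimConfig fields by name (isoscape nested)

Round trip is exact to CSV precision; identical (config, seed) pairs give
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import date
from pathlib import Path

import pandas as pd

from .simulate import Isoscape, SimBird, SimConfig

__all__ = ["write_bird", "read_sensor_csv", "config_to_json", "config_from_json"]


def write_bird(bird: SimBird, out_dir) -> Path:
    """Write one simulated bird's sensor streams + ground truth to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bird.light.to_csv(out / "light.csv", index=False, float_format="%.6g")
    bird.immersion.to_csv(out / "immersion.csv", index=False)
    if len(bird.temperature):
        bird.temperature.to_csv(out / "temperature.csv", index=False, float_format="%.6g")
    bird.feathers.to_csv(out / "feathers.csv", index=False, float_format="%.6g")
    truth = {k: (v.isoformat() if isinstance(v, pd.Timestamp) else v) for k, v in bird.truth.items()}
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    (out / "config.json").write_text(config_to_json(bird.config) + "\n")
    return out


def read_sensor_csv(path) -> pd.DataFrame:
    """Read any of the sensor CSVs, parsing ``bin_start``/``grown_date``."""
    df = pd.read_csv(path)
    for col in ("bin_start", "grown_date"):
        if col in df:
            df[col] = pd.to_datetime(df[col])
    return df


def config_to_json(config: SimConfig) -> str:
    d = dataclasses.asdict(config)
    d["season_start"] = config.season_start.isoformat()
    return json.dumps(d, indent=2)


def config_from_json(text: str) -> SimConfig:
    d = json.loads(text)
    d["season_start"] = date.fromisoformat(d["season_start"])
    d["isoscape"] = Isoscape(**d["isoscape"])
    return SimConfig(**d)
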