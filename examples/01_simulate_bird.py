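"""Simulate one post-breeding season and write the device files.

Builds a subantarctic bird with the default configuration (colony at
49.47S 69.95E, late-February departure, ~2450 km south-west migration,
moult peaking 35 days after departure), renders its light / immersion /
temperature streams and feathers, and writes them as CSV next to a
truth.json of the ground-truth scalars.
"""

import petrelgls as pg

cfg = pg.SimConfig(seed=1)
bird = pg.simulate_bird(cfg)
out = pg.io.write_bird(bird, "scratch/example_bird")

tr = bird.truth
print(f"wrote {out}/light.csv, immersion.csv, temperature.csv, feathers.csv, truth.json")
print(f"departure {tr['departure_date'].date()}  return {tr['return_date'].date()}  "
      f"moult peak {tr['moult_peak_date'].date()}")
print(f"max range {tr['max_range_km']:.0f} km  total distance {tr['total_distance_km']:.0f} km")
print("These are the ground truths the analysis pipeline must recover from the")
print("sensor streams alone (the positions themselves are never recorded by a GLS).")
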