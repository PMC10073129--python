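#!/usr/bin/env python
"""Generate the analyte cohorts used by the downstream analyses.

One annotated trace per analyte under the standard study conditions
(open-pore current 500 pA at +100 mV, 2 % broadband white noise,
calibrated level-switching profiles).  The free protein is acquired at
100 kHz because its minor-level sojourns are sub-millisecond; the slowly
switching complexes are acquired at 25 kHz.

Writes results/cohorts/<analyte>.h5 (+ .annotation.json) and an index CSV.
"""

from pathlib import Path

import pandas as pd

from nanofp import profiles
from nanofp.generate import NoiseModel, generate_event_train
from nanofp.io import write_annotation, write_trace

OUT = Path("results/cohorts")
OUT.mkdir(parents=True, exist_ok=True)

SEED = 31
COHORTS = {
    # label: (sampling rate Hz, duration s)
    "free_bclxl": (100_000.0, 60.0),
    "bak_bh3_complex": (25_000.0, 180.0),
    "abt737_complex": (25_000.0, 120.0),
}

noise = NoiseModel(white_rms=10.0)
rows = []
for i, (label, (fs, duration)) in enumerate(COHORTS.items()):
    profile = profiles.make_profile(label, sampling_rate=25_000.0)
    trace, ann = generate_event_train(profile, noise, 500.0, fs, duration, seed=SEED + i)
    write_trace(trace, OUT / f"{label}.h5")
    write_annotation(ann, OUT / f"{label}.annotation.json")
    rows.append(
        {
            "analyte": label,
            "sampling_rate_hz": fs,
            "duration_s": duration,
            "n_events_true": len(ann.events),
            "trace_file": f"{label}.h5",
        }
    )
    print(f"{label}: {len(ann.events)} events over {duration:.0f} s at {fs / 1000:.0f} kHz")

pd.DataFrame(rows).to_csv(OUT / "index.csv", index=False)
print(f"\nCohorts written to {OUT}/ — downstream scripts (04–06) read these files.")
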