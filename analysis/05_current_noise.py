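#!/usr/bin/env python
"""Current-noise (I_N) analysis of the simulated cohorts.

Refilters each detected event at 100 Hz / 1 kHz / 10 kHz with the causal
8-pole Bessel, integrates the periodogram (first non-DC bin excluded) and
reports cohort mean ± SD per cutoff.  The 100 Hz column is the
discriminating statistic: the slowly switching peptide complex retains
almost its full level-fluctuation RMS below 100 Hz, while the fast-
switching free protein loses most of it.

Reads results/cohorts/; writes results/current_noise.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nanofp.events import detect_events, estimate_open_current
from nanofp.io import read_trace
from nanofp.noise import cohort_IN

COHORTS = Path("results/cohorts")
OUT = Path("results")
CUTOFFS = (100.0, 1000.0, 10_000.0)

rows = []
for path in sorted(COHORTS.glob("*.h5")):
    label = path.stem
    trace = read_trace(path)
    Io = estimate_open_current(trace)
    events = detect_events(trace, Io, min_duration=0.01)
    for cutoff in CUTOFFS:
        if cutoff >= trace.sampling_rate / 2:
            continue
        results, dropped = cohort_IN(events, trace, cutoff)
        vals = np.array([r.I_N for r in results])
        rows.append(
            {
                "analyte": label,
                "cutoff_hz": cutoff,
                "mean_IN_pA": round(float(vals.mean()), 1) if vals.size else None,
                "sd_IN_pA": round(float(vals.std()), 1) if vals.size else None,
                "n_events": int(vals.size),
                "dropped_short": dropped,
            }
        )

df = pd.DataFrame(rows)
df.to_csv(OUT / "current_noise.csv", index=False)
print(df.to_string(index=False))

at100 = df[df.cutoff_hz == 100.0].set_index("analyte")["mean_IN_pA"]
print(
    f"\nAt the 100 Hz cutoff the cohorts separate cleanly: free protein "
    f"{at100.get('free_bclxl')} pA, small-molecule complex "
    f"{at100.get('abt737_complex')} pA, peptide complex "
    f"{at100.get('bak_bh3_complex')} pA — the low-frequency noise axis of the"
    " 2D fingerprint."
)
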