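#!/usr/bin/env python
"""Drug-competition displacement monitored over time.

A pre-formed peptide complex is displaced by a competing small molecule
with first-order kinetics: the displaced fraction follows 1 − e^{−kt}.
Event labels are sampled per observation window, and the rate is fit back
from the windowed fractions — the time-course readout of a competition
experiment.

Writes results/competition_timecourse.csv and results/competition_fit.json.
"""

import json
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from nanofp.generate import generate_competition_timecourse

OUT = Path("results")
OUT.mkdir(exist_ok=True)

K_TRUE = 1.5e-3  # s^-1: ~8 min half-life, resolvable over a 40 min recording
WINDOWS = [0.0, 300.0, 600.0, 1200.0, 1800.0, 2400.0]
EVENTS_PER_WINDOW = 300

table = generate_competition_timecourse(
    "bak_bh3_complex", "abt737_complex", K_TRUE, WINDOWS, EVENTS_PER_WINDOW, seed=51
)
table.to_csv(OUT / "competition_timecourse.csv", index=False)

popt, pcov = curve_fit(
    lambda t, k: 100.0 * (1.0 - np.exp(-k * t)),
    table["time_s"],
    table["fraction_displaced_pct"],
    p0=[1e-3],
)
fit = {
    "k_true_per_s": K_TRUE,
    "k_fit_per_s": float(popt[0]),
    "k_fit_se": float(np.sqrt(pcov[0, 0])),
    "half_life_min_fit": float(np.log(2) / popt[0] / 60.0),
}
(OUT / "competition_fit.json").write_text(json.dumps(fit, indent=1))
print(table.to_string(index=False))
print(
    f"\nFitted displacement rate k = {fit['k_fit_per_s']:.2e} ± "
    f"{fit['k_fit_se']:.1e} s⁻¹ (true {K_TRUE:.2e}); half-life "
    f"{fit['half_life_min_fit']:.1f} min.  After ~40 min the initial peptide-"
    "complex population is essentially fully displaced by the competing drug."
)
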