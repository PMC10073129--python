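# nanofp — single-molecule nanopore fingerprinting of protein–drug interactions

`nanofp` is a toolkit for analyzing — and, because no raw
electrophysiology data are deposited, for *simulating* — single-molecule
current recordings from a funnel-shaped biological nanopore that traps
folded proteins by electro-osmotic flow.  It is written for people who
work with protein nanopore sensors: the target use case is label-free
detection of protein–drug interactions (PDIs), where a trapped protein's
ionic-current signature changes when a peptide or small-molecule ligand
binds it.

## The science in brief

A protein trapped in a funnel pore partially blocks the open-pore current
I_o.  Thermal motion between residence sites along the pore axis produces
discrete blockade levels L1–L3 within each capture–trap–escape event.
Two per-event statistics carry the binding information:

* **ΔI/I_o** — the normalized current blockade (%), computed from the
  event's median current;
* **I_N** — the current noise (pA): the RMS of the event's fluctuations,
  `I_N = sqrt(Σ P_i·Δf)` over the one-sided periodogram of the
  mean-removed event after refiltering at 100 Hz (first non-DC bin
  excluded), which isolates the slow level-switching dynamics.

Complexes switch between levels slowly and with large amplitude, so they
carry far more sub-100 Hz power than free protein; the (ΔI/I_o, I_N)
plane separates free protein, peptide complex, and drug complexes into
distinct populations ("drug fingerprints").  Counting complexed vs total
events along a ligand titration gives the bound fraction
F_c = N_comp/N_total × 100, fit by the one-site curve
`Y = B_max·X/(K_D + X)` for the dissociation constant.

Pore-side utilities cover funnel conductance
`G = σ_s·π·d_in·d_out/(4L)`, the Goldman–Hodgkin–Katz permeability ratio
from a measured reversal potential, and ion-flux→current conversion.
The synthetic-trace generator is two-tier: a Brownian-dynamics integrator
(`z(t+Δt) = z(t) + (D/kT)F(z)Δt + S`, Var S = 2DΔt) validates the
double-well physics, and a calibrated continuous-time Markov chain over
blockade levels produces seconds-long annotated traces whose occupancies
and low-frequency noise match published cohort statistics.  See
`docs/methods.md` for the full model description.

## Worked example

Pore characterization from the command line:

```
$ nanofp pore
pore C8: L=18.0 nm, d_cis=10.0 nm, d_constriction=1.9 nm
funnel conductance (cis entry x constriction): 8.70 nS
GHK selectivity at Vr=11.7 mV: P_K/P_Cl = 2.34
```

The 8.70 nS is the theoretical funnel conductance for an 18 nm pore with
a 10 nm entry and 1.9 nm constriction in a 10.5 S/m electrolyte; the
2.34 cation/anion permeability ratio (from the 11.7 mV reversal potential
under a 2 M/0.5 M KCl gradient) is the strong cation selectivity that
drives electro-osmotic trapping.

The same analysis in Python, end to end on synthetic data:

```python
from nanofp import profiles
from nanofp.generate import NoiseModel, generate_event_train
from nanofp.events import estimate_open_current, detect_events
from nanofp.levels import segment_levels, open_probabilities

profile = profiles.make_profile("bak_bh3_complex")   # calibrated peptide-complex profile
trace, truth = generate_event_train(profile, NoiseModel(white_rms=10.0),
                                    Io=500.0, sampling_rate=25_000.0,
                                    duration=180.0, seed=31)
Io = estimate_open_current(trace)
events = detect_events(trace, Io, min_duration=0.01)
segs = [s for ev in events for s in segment_levels(ev, trace)]
print(open_probabilities(segs, trace.sampling_rate).open_probability_pct)
```

Running the numbered drivers under `analysis/` prints, among others
(`python analysis/03_simulate_cohorts.py` then `04` and `05`):

```
        analyte level  recovered_pct  se_pct  configured_pct
bak_bh3_complex    L1          42.55    0.93           42.13
bak_bh3_complex    L2          57.37    0.93           57.71
     free_bclxl    L2          90.85    1.40           91.25

        analyte  cutoff_hz  mean_IN_pA  sd_IN_pA
     free_bclxl      100.0        17.2       2.4
 abt737_complex      100.0        28.4       2.8
bak_bh3_complex      100.0        79.7       2.8
```

Blind detection + segmentation recovers the configured level occupancies
within ~1 SE, and the 100 Hz current-noise axis separates the three
analytes by factors of 2–5 — the discrimination mechanism the fingerprint
relies on.  Script `06` classifies pooled single events against per-analyte
reference fingerprints at 99.4 % accuracy; `07` fits dissociation
constants of 19/38/66 nM ligands from binomial titrations; `08` recovers
a first-order drug-displacement rate from a windowed time-course.

## Analysis pipeline

```
analysis/01_pore_characterization.py   conductance, GHK selectivity, flux→current
analysis/02_landscape_and_brownian.py  double-well Brownian dynamics + validation
analysis/03_simulate_cohorts.py        annotated analyte traces (results/cohorts/)
analysis/04_level_occupancies.py       blind L1–L3 open probabilities
analysis/05_current_noise.py           I_N vs filter cutoff per analyte
analysis/06_fingerprint_screening.py   2D fingerprint classification
analysis/07_titration_binding.py       K_D / B_max one-site fits
analysis/08_competition_timecourse.py  displacement kinetics
```

Each script is a thin driver over the library in `src/nanofp/` and writes
its tables under `results/`.  The `nanofp` CLI exposes the same stages
(`simulate`, `detect`, `levels`, `noise`, `fingerprint`, `titrate`,
`compete`, `pore`, `run`); `nanofp run` executes the whole seeded demo
pipeline and writes a manifest, with byte-identical numeric outputs for
identical (config, seed).

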