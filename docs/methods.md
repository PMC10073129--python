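# Methods

## The measurement being modeled

A funnel-shaped protein nanopore (the C8 oligomer of the YaxA/YaxB
pore-forming toxin) sits in a lipid bilayer under an applied potential.
Its strong cation selectivity drives an electro-osmotic flow that captures
folded proteins from the *cis* side and holds them in the funnel against
the opposing electrophoretic force.  A trapped protein partially blocks
the ionic current; because the funnel narrows toward the constriction,
the blockade depends sharply on *where* along the pore axis the protein
resides.  Thermal motion between two residence sites (near z ≈ 4 nm and
z ≈ 10 nm from the membrane) produces discrete blockade levels L1–L3
within a single trapping event, and ligand binding changes both the level
statistics and the low-frequency fluctuation power of the event.  Those
two observables — the normalized blockade ΔI/I_o and the current noise
I_N — form a 2D per-event fingerprint that discriminates drug-bound
complexes from free protein.

## Pore biophysics

Closed-form utilities, each a direct evaluation of a standard expression:

* **Funnel conductance.** A tapered channel of length L between diameters
  d_in and d_out has resistance R = 4L/(σ_s π d_in d_out); the package
  returns G = 1/R in nS (σ_s in S/m, lengths in nm).  With d_in = d_out
  this is exactly the uniform-cylinder formula.  Which physical diameters
  play d_in/d_out is an explicit argument (default: cis entry ×
  constriction) because conductance-derived size estimates depend on that
  choice.
* **GHK selectivity.** For a single binary salt with activities a = γ·c,
  P_K/P_Cl = (a_cis − a_trans e^x)/(a_cis e^x − a_trans), x = V_r F/RT.
  Activity coefficients 0.573 (2 M KCl) and 0.649 (0.5 M KCl); RT/F =
  25.693 mV at 298.15 K.  The expression is singular at the K⁺ Nernst
  potential; outside the interval between the two Nernst potentials it
  changes sign and the function raises rather than returning a negative
  ratio.
* **Flux → current.** I = rate·|z|·e; 1 ns⁻¹ of a monovalent ion is
  160.218 pA.

## Brownian-dynamics tier

The microscopic model is overdamped 1D diffusion in a potential of mean
force ΔG(z) over z ∈ [2, 13] nm:

    z(t+Δt) = z(t) + (D/kT)·F(z)·Δt + S,   S ~ N(0, 2DΔt)

with F = −dΔG/dz by finite differences, D = 10 nm²/µs, Δt = 10⁻⁴ µs.
The "width 2DΔt" of the noise term is read as its *variance* (the
standard Ermak–McCammon convention), giving a step σ of 0.0447 nm at the
defaults.  z = 2 nm (constriction) is reflecting; z = 13 nm is absorbing
and models escape to the *cis* side.  Landscapes are monotone-segment
PCHIP curves through control points: a wall at the constriction, two well
anchors (energy differences preserved exactly, kcal/mol converted at
298.15 K where 1 kcal/mol = 1.688 kT), a single interior barrier of
configurable height, and a modest escape barrier.  The integrator is
validated against free-diffusion MSD = 2Dt, the harmonic-well variance
kT/κ, and Boltzmann well occupancies (per-walker fractions give honest
standard errors).

The position→current map is linear interpolation over residence-site
anchors: 35 % residual current at z = 4 nm and 73 % at z = 10 nm (the
deep site blocks ~38 points more), clamped outside; an escaped protein
emits the open-pore current.

A direct Eq.-style integration of seconds of trace would need ~10¹⁰
steps, so the long-trace generator uses a second tier.

## Level-switching (CTMC) tier and its calibration

Within an event the emitted level follows a continuous-time Markov chain
over L1–L3 with a reversible star topology through the dominant level.
The stationary distribution is fixed to the published open probabilities
(free protein 4.98/91.25/3.77 %; peptide complex 42.13/57.71/0.16 %;
small-molecule complex 13.29/86.66/0.05 %).  Capture is Poisson (rate
1/τ_on); dwell times are exponential (mean τ_off); broadband white noise
(default 10 pA RMS = 2 % of the 500 pA open-pore current) and optional
1/f noise are added on top; an optional causal 8-pole Bessel "hardware"
filter can be applied.  Annotations (event and level-segment intervals,
0-based half-open) are exact, and all randomness flows from one
`numpy` Generator, so output is bit-reproducible given (seed, parameters).

The one quantity the published statistics do *not* pin is the switching
timescale.  It is calibrated, not hand-tuned: for a reversible chain the
level-process autocovariance is a sum of exponentials, so its one-sided
PSD is a sum of Lorentzians obtained from the symmetrized generator
D^{1/2}QD^{−1/2}.  The expected *measured* I_N of the full analysis chain
is computed analytically — CTMC spectrum plus white floor, weighted by
the squared magnitude response of the actual digital 100 Hz Bessel
refilter and by the finite-window kernel

    K_T(f) = 1 − sinc²(fT) − sinc²(fT−1) − sinc²(fT+1)

(mean removal empties the DC bin; the excluded first bin removes a sinc²
lobe of width 1/T), averaged over the event-duration distribution, with a
chi-square correction for the concavity of the square root.  A single
rate-scale factor is then solved (Brent) so this expectation equals the
published cohort I_N: 16.3 pA (free), 78.9 pA (peptide complex), 28.2 pA
(drug complex), 36.3 pA (second drug complex).  The solution is taken on
the fast-switching branch past the unimodal peak.  The calibrated rates
land where the physics says they should: the peptide complex alternates
at ~10 ms sojourns (power concentrated below 100 Hz), the free protein at
~0.4 ms (power mostly above the cutoff) — slow, large-amplitude
level-switching is precisely what makes complexes noisy at low frequency.

Default event kinetics: τ_off = 0.2 s / capture 5 s⁻¹ (free), 0.5 s /
2 s⁻¹ (peptide complex), 0.3 s / 3 s⁻¹ (drug complexes).  The free-protein
dwell is chosen so that events resolve the 100 Hz band with many
periodogram bins (Δf = 1/T ≈ 5 Hz); the occupancies of the second drug
complex (no published values) assume two-level alternation like the other
complexes and are noted as package defaults.

## Analysis conventions

* **Open-pore current.** Mode of the highest-current amplitude-histogram
  population, refined by a Gaussian fit; fails loudly when no population
  holds ≥ 10 % of samples or no mode towers over the histogram
  background.
* **Event detection.** Hysteresis thresholds: an event opens below
  0.85·I_o and closes at 0.95·I_o, minimum duration configurable
  (analyses here use 10 ms).  On noiseless generator output the detected
  boundaries equal the annotations sample-exactly.
* **Blockade.** ΔI/I_o of an event is computed from the event's *median*
  current — dominated by the event's dominant level, insensitive to
  brief spikes.  Cohort statistics are the peak of a Gaussian fit to the
  per-event histogram, with a bimodality flag (two prominent modes).
* **Level segmentation.** Per-event Gaussian mixture over sample
  amplitudes (≤ 3 components), initialized at amplitude-histogram peaks
  (a generic initialization misses few-percent minor levels beside a
  > 90 % dominant level), components closer than 2σ merged, runs shorter
  than 5 samples absorbed into the nearest-mean neighbor, labels ranked
  by residual current (L1 shallowest).  Open probabilities are
  time-weighted; standard errors come from the spread of per-event
  fractions.
* **I_N.** Plain (unwindowed) one-sided periodogram of the mean-removed
  segment, exactly Parseval-normalized; I_N = √(∫PSD df) over retained
  bins with the first non-DC bin excluded (edge-leakage lands there; the
  exclusion count is a parameter).  Refiltering at 100 Hz/1 kHz/10 kHz
  uses the causal 8-pole Bessel with reflect-padded startup (priming the
  filter state from a single sample injects a low-frequency transient
  that corrupts the 100 Hz statistic).  Cohort I_N means use only events
  ≥ 0.3 s — shorter events cannot resolve sub-100 Hz power (their bin
  width rivals the cutoff), and including them makes the statistic
  duration-dependent rather than analyte-dependent.
* **Fingerprints and populations.** Per-event points (ΔI/I_o, I_N at
  100 Hz); populations are full-covariance 2D Gaussian mixtures with
  maximum-posterior assignment (ties to the lowest component index);
  optional normalization by a free-protein reference cohort's means.  In
  the screening analysis each analyte's reference fingerprint is fit on
  its own cohort first and pooled events are classified against the
  references, mirroring the experimental workflow.
* **Binding.** F_c = N_comp/N_total × 100; one-site curve
  Y = B_max·X/(K_D+X) fit by unweighted nonlinear least squares (optional
  binomial weighting), 95 % CIs from the t-distribution on the fit
  covariance.  The titration generator draws binomial counts with success
  probability B_max·X/(K_D+X) capped at 1; because B_max > 1 implies
  saturation above ~170 nM for the tightest binder, the plain fit on a
  1–500 nM grid is biased low by ~2 nM — visible and documented, not
  corrected, since the analysis model is the plain one-site curve.
* **Competition.** First-order exchange: displaced fraction 1 − e^(−kt),
  labels sampled binomially per observation window.

## Problem sizes

Cohort analyses use ≥ 300 events: the free protein at 100 kHz (its
~0.4 ms minor-level sojourns need tens of samples each; 130–140 s of
trace), the slowly switching complexes at 25 kHz (360 s).  Titrations use
9 log-spaced concentrations from 1 to 500 nM with 300 events per point.
Brownian validation uses ensembles of 150–400 walkers over 2 k–80 k
steps.  These sizes put every stochastic recovery within a few standard
errors of its target while a full analysis run completes in about a
minute.

## What the generator does and does not emulate

Emulated: open-pore baseline with white (and optionally 1/f) noise,
capture–trap–escape events with exponential kinetics, 2–3 discrete
residual-current levels with occupancies and low-frequency noise matched
to the published cohort statistics, hardware-style causal Bessel
filtering, binomial titration counts, first-order displacement.

Not emulated: baseline drift and pore gating; correlated/flicker noise of
real amplifiers beyond the optional 1/f term; within-level current
substructure (levels are ideal plateaus plus noise); voltage dependence of
occupancies and residual currents (the voltage-trend analysis is
exercised on configured synthetic slopes); capture-rate dependence on
analyte concentration and charge; any conformational dynamics of the
protein itself.  Passing tests therefore demonstrate that the *analysis
chain* recovers the statistical structure the model family encodes — not
that real recordings obey that family.

## Known limitations

* The blockade of a multi-level event is its median-current blockade;
  for complexes with near-50/50 level occupancy the per-event median can
  flip between levels, broadening the fingerprint's blockade axis.
* The GHK implementation is restricted to a single binary salt on each
  side.
* The Brownian tier and the CTMC tier are linked conceptually (residence
  sites ↔ levels) but switch rates are calibrated to noise data, not
  derived from mean first-passage times of the landscape; the published
  100 mV landscape (ΔΔG ≈ 21.5 kT) would freeze the protein in the deep
  well, contradicting the observed level mixing, so the demonstration
  landscape uses kT-scale wells.
* K_D recovery inherits the saturation-cap bias described above whenever
  B_max > 1.
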