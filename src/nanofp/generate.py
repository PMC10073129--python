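"""Synthetic trace generation: events, titrations, competition time-courses.

Two tiers of physics feed the generator.  The Brownian-dynamics integrator
(:mod:`nanofp.brownian`) validates the microscopic picture — diffusion in
a double-well landscape with a position→current map — but at its native
0.1 ns timestep it cannot produce seconds of trace.  Long annotated traces
therefore come from a continuous-time Markov chain over discrete blockade
levels whose stationary occupancies and switching rates are calibrated to
the published level statistics (:mod:`nanofp.profiles`).

Every stochastic operation takes a seed (or Generator) and is
bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ctmc
from .events import Trace
from .filters import bessel_filter_array

__all__ = [
    "CurrentMap",
    "NoiseModel",
    "AnalyteProfile",
    "SegmentAnnotation",
    "EventAnnotation",
    "GroundTruthAnnotation",
    "position_to_current",
    "generate_event_train",
    "generate_titration",
    "generate_competition_timecourse",
    "DEFAULT_CURRENT_MAP",
]


@dataclass(frozen=True)
class CurrentMap:
    """Monotone map from axial position to residual current.

    Deeper positions (small z, near the constriction) block more current.
    Anchors are ``(z nm, residual % of I_o)`` pairs; between anchors the
    residual fraction is interpolated linearly and clamped outside.
    """

    anchor_points: tuple[tuple[float, float], ...]
    open_pore_current_Io: float = 500.0  # pA

    def __post_init__(self) -> None:
        z = np.array([a[0] for a in self.anchor_points])
        r = np.array([a[1] for a in self.anchor_points])
        if z.size < 2 or np.any(np.diff(z) <= 0):
            raise ValueError("anchor z positions must be strictly increasing")
        if np.any(np.diff(r) < 0):
            raise ValueError("residual fraction must be non-decreasing in z")
        if np.any((r < 0) | (r > 100)):
            raise ValueError("residual fractions must lie in [0, 100] %")

    def residual_pct(self, z) -> np.ndarray:
        zs = np.array([a[0] for a in self.anchor_points])
        rs = np.array([a[1] for a in self.anchor_points])
        return np.interp(z, zs, rs)


#: Residence-site anchors: the deep site (z = 4 nm) leaves ~35 % residual
#: current at 100 mV and the shallow site (z = 10 nm) ~38 points more.
DEFAULT_CURRENT_MAP = CurrentMap(anchor_points=((4.0, 35.0), (10.0, 73.0)))


def position_to_current(
    trajectory: np.ndarray, cmap: CurrentMap = DEFAULT_CURRENT_MAP
) -> np.ndarray:
    """Ideal (noiseless) current for a positional trajectory, in pA.

    NaN samples mark an unoccupied pore (after escape) and emit I_o.
    """
    z = np.asarray(trajectory, dtype=float)
    out = np.full(z.shape, cmap.open_pore_current_Io)
    occ = np.isfinite(z)
    out[occ] = cmap.residual_pct(z[occ]) / 100.0 * cmap.open_pore_current_Io
    return out


@dataclass(frozen=True)
class NoiseModel:
    """Additive instrument noise.

    ``white_rms`` is the broadband white-noise RMS in pA at the full
    acquisition bandwidth.  The optional flicker component has one-sided
    PSD ``flicker_amplitude / f^flicker_exponent`` (pA²/Hz at 1 Hz) and is
    synthesized spectrally per trace.
    """

    white_rms: float = 10.0  # pA
    flicker_amplitude: float = 0.0  # pA²·Hz^(exponent-1)
    flicker_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.white_rms < 0:
            raise ValueError("white_rms must be non-negative")
        if not (0.5 <= self.flicker_exponent <= 2.0):
            raise ValueError("flicker exponent must lie in [0.5, 2]")

    def sample(self, n: int, sampling_rate: float, rng: np.random.Generator) -> np.ndarray:
        noise = self.white_rms * rng.standard_normal(n)
        if self.flicker_amplitude > 0 and n > 2:
            freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
            psd = np.zeros_like(freqs)
            psd[1:] = self.flicker_amplitude / freqs[1:] ** self.flicker_exponent
            # one-sided PSD -> rfft amplitude scaling
            amp = np.sqrt(psd * sampling_rate * n / 2.0)
            phases = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
            phases[0] = 0.0
            noise = noise + np.fft.irfft(amp * phases / np.sqrt(2.0), n=n)
        return noise


@dataclass(frozen=True, eq=False)
class AnalyteProfile:
    """Per-analyte event statistics driving the long-trace generator.

    ``level_switch_rates`` is a full CTMC rate matrix (s⁻¹) over the
    levels; its stationary distribution must match ``level_occupancies``
    (that is checked at construction, so occupancies and dynamics cannot
    drift apart silently).
    """

    label: str
    level_residual_fractions: tuple[float, ...]  # % of Io, ordered L1 (shallow) .. L3
    level_occupancies: tuple[float, ...]
    level_switch_rates: np.ndarray  # (K, K) rate matrix, s⁻¹
    mean_dwell_tau_off: float  # s
    capture_rate_1_over_tau_on: float  # s⁻¹

    def __post_init__(self) -> None:
        occ = np.asarray(self.level_occupancies, dtype=float)
        res = np.asarray(self.level_residual_fractions, dtype=float)
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError("level occupancies must sum to 1")
        if np.any(occ < 0):
            raise ValueError("occupancies must be non-negative")
        if np.any(np.diff(res) > 0):
            raise ValueError("residual fractions must be ordered L1 (largest) downward")
        if self.mean_dwell_tau_off <= 0 or self.capture_rate_1_over_tau_on < 0:
            raise ValueError("dwell and capture parameters must be positive")
        Q = ctmc.validate_rate_matrix(self.level_switch_rates)
        if Q.shape[0] != occ.size:
            raise ValueError("rate matrix size must match the number of levels")
        if np.abs(Q).max() > 0:
            pi = ctmc.stationary_distribution(Q)
            if not np.allclose(pi, occ, atol=1e-6):
                raise ValueError(
                    "stationary distribution of the switch rates does not match "
                    f"the configured occupancies (got {pi}, want {occ})"
                )

    @property
    def n_levels(self) -> int:
        return len(self.level_occupancies)

    def level_currents(self, Io: float) -> np.ndarray:
        return np.asarray(self.level_residual_fractions) / 100.0 * Io


@dataclass(frozen=True)
class SegmentAnnotation:
    start_index: int
    end_index: int  # half-open
    level_index: int  # 0 = L1


@dataclass(frozen=True)
class EventAnnotation:
    start_index: int
    end_index: int  # half-open
    segments: tuple[SegmentAnnotation, ...]
    analyte_label: str


@dataclass
class GroundTruthAnnotation:
    events: list[EventAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            segs = ev.segments
            if not segs:
                raise ValueError("event without segments")
            if segs[0].start_index != ev.start_index or segs[-1].end_index != ev.end_index:
                raise ValueError("segments must tile the event interval")
            for a, b in zip(segs[:-1], segs[1:]):
                if a.end_index != b.start_index:
                    raise ValueError("segments must tile without gaps or overlap")


def generate_event_train(
    profile: AnalyteProfile,
    noise: NoiseModel,
    Io: float,
    sampling_rate: float,
    duration: float,
    seed: int | np.random.Generator,
    hardware_filter_hz: float | None = None,
    voltage_mv: float = 100.0,
) -> tuple[Trace, GroundTruthAnnotation]:
    """Generate an annotated trace of capture–trap–escape events.

    Inter-event waiting times are exponential with rate ``1/τ_on``, event
    durations exponential with mean ``τ_off``; within an event the level
    follows the profile's CTMC started from its stationary distribution.
    Annotations are exact sample intervals of the noiseless level process;
    with zero noise and no hardware filter the emitted samples equal the
    configured level currents exactly.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if hardware_filter_hz is not None and sampling_rate < 2 * hardware_filter_hz:
        raise ValueError("sampling rate must be at least twice the hardware cutoff")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    current = np.full(n, float(Io))
    ann = GroundTruthAnnotation()
    level_I = profile.level_currents(Io)
    Q = np.asarray(profile.level_switch_rates, dtype=float)

    t = 0.0
    while True:
        if profile.capture_rate_1_over_tau_on <= 0:
            break
        t += rng.exponential(1.0 / profile.capture_rate_1_over_tau_on)
        ev_dur = rng.exponential(profile.mean_dwell_tau_off)
        start = int(np.ceil(t * sampling_rate))
        end = int(np.ceil((t + ev_dur) * sampling_rate))
        if start >= n:
            break
        end = min(end, n)
        if end <= start:
            t += ev_dur
            continue
        states, times = ctmc.sample_path(Q, (end - start) / sampling_rate, rng)
        bounds = np.concatenate(
            [
                start + np.minimum(np.ceil(times * sampling_rate).astype(int), end - start),
                [end],
            ]
        )
        segs = []
        for k, st in enumerate(states):
            s, e = int(bounds[k]), int(bounds[k + 1])
            if e <= s:
                continue
            current[s:e] = level_I[st]
            if segs and segs[-1].level_index == st:
                segs[-1] = SegmentAnnotation(segs[-1].start_index, e, int(st))
            else:
                segs.append(SegmentAnnotation(s, e, int(st)))
        if segs:
            # re-tile to drop zero-length leading/trailing artifacts
            segs[0] = SegmentAnnotation(start, segs[0].end_index, segs[0].level_index)
            segs[-1] = SegmentAnnotation(segs[-1].start_index, end, segs[-1].level_index)
            ann.events.append(
                EventAnnotation(
                    start_index=start,
                    end_index=end,
                    segments=tuple(segs),
                    analyte_label=profile.label,
                )
            )
        t += ev_dur

    current = current + noise.sample(n, sampling_rate, rng)
    filter_state = []
    if hardware_filter_hz is not None:
        current = bessel_filter_array(current, hardware_filter_hz, sampling_rate)
        filter_state.append(("bessel", 8, float(hardware_filter_hz)))
    trace = Trace(
        current_pA=current,
        sampling_rate=sampling_rate,
        applied_voltage_mv=voltage_mv,
        filter_state=filter_state,
        provenance=f"synthetic:{profile.label}",
    )
    return trace, ann


def generate_titration(
    KD: float,
    Bmax: float,
    concentrations: list[float],
    events_per_point: int,
    seed: int | np.random.Generator,
    strict: bool = False,
) -> pd.DataFrame:
    """Binomial titration counts under one-site binding.

    At ligand concentration X the probability that a trapped-protein event
    is ligand-bound is ``Bmax·X/(KD + X)``, capped at 1 (``strict=True``
    raises instead of capping).  Returns a table with columns
    ``concentration_nM, N_comp, N_total, F_c_pct``.
    """
    if KD <= 0:
        raise ValueError("KD must be positive")
    if events_per_point <= 0:
        raise ValueError("events_per_point must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(concentrations, dtype=float)
    p = Bmax * X / (KD + X)
    if np.any(p > 1.0):
        if strict:
            raise ValueError("bound probability exceeds 1 at the requested concentrations")
        p = np.minimum(p, 1.0)
    n_comp = rng.binomial(events_per_point, p)
    return pd.DataFrame(
        {
            "concentration_nM": X,
            "N_comp": n_comp,
            "N_total": events_per_point,
            "F_c_pct": n_comp / events_per_point * 100.0,
        }
    )


def generate_competition_timecourse(
    initial_population: str,
    competitor_population: str,
    displacement_rate_k: float,
    observation_windows: list[float],
    events_per_window: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """First-order displacement: fraction displaced at time t is 1 - e^{-kt}.

    Each observation window (time in s) yields ``events_per_window``
    labeled events sampled from the instantaneous mixture.  Returns
    ``time_s, n_initial, n_competitor, fraction_displaced_pct``.
    """
    if displacement_rate_k < 0:
        raise ValueError("displacement rate must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for t in observation_windows:
        p_disp = 1.0 - np.exp(-displacement_rate_k * t)
        n_disp = int(rng.binomial(events_per_window, p_disp))
        rows.append(
            {
                "time_s": float(t),
                "initial_label": initial_population,
                "competitor_label": competitor_population,
                "n_initial": events_per_window - n_disp,
                "n_competitor": n_disp,
                "fraction_displaced_pct": n_disp / events_per_window * 100.0,
            }
        )
    return pd.DataFrame(rows)
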