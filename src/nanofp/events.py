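"""Event detection and per-event blockade/dwell statistics.

A raw trace alternates between open-pore baseline (current ≈ I_o) and
capture–trap–escape events during which the current drops to one or more
blockade levels.  Detection uses hysteresis thresholding: an event opens
when the current falls below ``entry·I_o`` and closes when it recovers
above ``exit·I_o`` (entry < exit), which tolerates shallow L1 levels near
baseline without chattering.  Blockade of a multi-level event is defined
from the event's median current, so it reflects the dominant level and is
insensitive to brief spikes.

All sample intervals are 0-based and half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "Trace",
    "EventRecord",
    "KineticsSummary",
    "EstimationError",
    "InsufficientDataError",
    "estimate_open_current",
    "detect_events",
    "inter_event_intervals",
    "blockade_statistics",
    "dwell_kinetics",
]


class EstimationError(RuntimeError):
    """No resolvable open-pore baseline population in the trace."""


class InsufficientDataError(RuntimeError):
    """Too few events for the requested statistic."""


@dataclass
class Trace:
    """Uniformly sampled ionic current with acquisition metadata."""

    current_pA: np.ndarray
    sampling_rate: float  # Hz
    applied_voltage_mv: float = 100.0
    filter_state: list = field(default_factory=list)  # [(type, poles, cutoff_hz), ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.current_pA)):
            raise ValueError("all current samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.current_pA.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class EventRecord:
    """One capture–trap–escape episode."""

    start_index: int
    end_index: int  # half-open
    Io_local: float  # pA
    mean_blockade_dIoverIo: float  # %
    median_residual_Ires: float  # % of Io
    dwell_time: float  # s
    event_id: int = -1

    def __post_init__(self) -> None:
        if self.start_index >= self.end_index:
            raise ValueError("event must satisfy start < end")
        if not (0.0 <= self.mean_blockade_dIoverIo <= 100.0):
            raise ValueError("blockade must lie in [0, 100] %")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    def samples(self, trace: Trace) -> np.ndarray:
        return trace.current_pA[self.start_index : self.end_index]


@dataclass
class KineticsSummary:
    tau_on: float  # s
    tau_off: float  # s
    capture_rate: float  # s⁻¹
    event_count: int
    tau_on_se: float
    tau_off_se: float


def estimate_open_current(
    trace: Trace, n_bins: int = 200, min_baseline_fraction: float = 0.10
) -> float:
    """Open-pore current I_o from the upper mode of the amplitude histogram.

    The baseline is the highest-current population; its peak is refined by
    a Gaussian fit around the histogram mode.  Raises ``EstimationError``
    when that population holds less than ``min_baseline_fraction`` of the
    samples (e.g. a trace that is blocked throughout).
    """
    x = trace.current_pA
    if x.size < 10:
        raise EstimationError("trace too short to estimate a baseline")
    if np.ptp(x) < 1e-12:
        return float(x[0])
    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # candidate population peaks, highest current last
    peaks, _ = find_peaks(counts, height=0.5 * counts.max())
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(counts))])
    top = peaks[-1]
    # a genuine amplitude mode towers over the histogram background; a
    # drifting or featureless trace does not
    background = np.median(counts[counts > 0])
    if counts[top] < 2.0 * background:
        raise EstimationError("no resolvable open-pore mode in the amplitude histogram")
    # mass of the candidate baseline population: samples within the peak's
    # half-maximum span
    half = counts[top] / 2.0
    lo = top
    while lo > 0 and counts[lo - 1] >= half:
        lo -= 1
    hi = top
    while hi < counts.size - 1 and counts[hi + 1] >= half:
        hi += 1
    width = max(edges[hi + 1] - edges[lo], (edges[1] - edges[0]) * 3)
    in_pop = np.abs(x - centers[top]) <= 1.5 * width
    if in_pop.mean() < min_baseline_fraction:
        raise EstimationError(
            "no resolvable open-pore population "
            f"(upper mode holds {in_pop.mean():.1%} of samples)"
        )
    sel = slice(max(lo - 2, 0), min(hi + 3, centers.size))
    try:
        popt, _ = curve_fit(
            lambda c, a, mu, s: a * np.exp(-0.5 * ((c - mu) / s) ** 2),
            centers[sel],
            counts[sel],
            p0=[counts[top], centers[top], max(width / 2.355, 1e-6)],
            maxfev=2000,
        )
        mu = float(popt[1])
        if not (edges[0] <= mu <= edges[-1]):
            mu = float(centers[top])
    except RuntimeError:
        mu = float(centers[top])
    return mu


def detect_events(
    trace: Trace,
    Io: float,
    entry_threshold_fraction: float = 0.85,
    exit_threshold_fraction: float = 0.95,
    min_duration: float = 0.0,
) -> list[EventRecord]:
    """Hysteresis event detection.

    An event spans the maximal interval starting at the first sample below
    ``entry·I_o`` and ending at the first sample at or above ``exit·I_o``;
    events shorter than ``min_duration`` are discarded.  Records are
    non-overlapping and time-ordered.
    """
    if Io <= 0:
        raise ValueError("Io must be positive")
    if not (0 < entry_threshold_fraction < exit_threshold_fraction < 1):
        raise ValueError("thresholds must satisfy 0 < entry < exit < 1")
    x = trace.current_pA
    enter = Io * entry_threshold_fraction
    leave = Io * exit_threshold_fraction
    min_samples = max(1, int(np.ceil(min_duration * trace.sampling_rate)))

    below_entry = x < enter
    above_exit = x >= leave
    events: list[EventRecord] = []
    i = 0
    n = x.size
    while i < n:
        if below_entry[i]:
            j = i + 1
            while j < n and not above_exit[j]:
                j += 1
            if j - i >= min_samples:
                seg = x[i:j]
                med = float(np.median(seg))
                blockade = float(np.clip((Io - med) / Io * 100.0, 0.0, 100.0))
                events.append(
                    EventRecord(
                        start_index=i,
                        end_index=j,
                        Io_local=Io,
                        mean_blockade_dIoverIo=blockade,
                        median_residual_Ires=100.0 - blockade,
                        dwell_time=(j - i) / trace.sampling_rate,
                        event_id=len(events),
                    )
                )
            i = j
        else:
            i += 1
    return events


def inter_event_intervals(events: list[EventRecord], sampling_rate: float) -> np.ndarray:
    """Waiting times (s) between the end of each event and the next start."""
    if len(events) < 2:
        return np.empty(0)
    starts = np.array([e.start_index for e in events[1:]], dtype=float)
    ends = np.array([e.end_index for e in events[:-1]], dtype=float)
    return (starts - ends) / sampling_rate


def blockade_statistics(
    events: list[EventRecord], n_bins: int = 40
) -> tuple[float, float, dict]:
    """Gaussian-fit peak of the per-event blockade histogram.

    Returns ``(peak %, sigma %, flags)``.  A clearly bimodal histogram
    raises the ``"bimodal"`` flag; a failed fit falls back to the sample
    mean with the ``"fallback_mean"`` flag.
    """
    if len(events) < 20:
        raise InsufficientDataError("need at least 20 events for a histogram fit")
    vals = np.array([e.mean_blockade_dIoverIo for e in events])
    flags: dict = {"bimodal": False, "fallback_mean": False}
    counts, edges = np.histogram(vals, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks, _ = find_peaks(counts, prominence=0.4 * counts.max(), distance=3)
    if peaks.size >= 2:
        flags["bimodal"] = True
    try:
        top = int(np.argmax(counts))
        popt, _ = curve_fit(
            lambda c, a, mu, s: a * np.exp(-0.5 * ((c - mu) / s) ** 2),
            centers,
            counts,
            p0=[counts[top], centers[top], max(vals.std(), 1e-6)],
            maxfev=5000,
        )
        peak, sigma = float(popt[1]), abs(float(popt[2]))
        if not (vals.min() - 5 <= peak <= vals.max() + 5):
            raise RuntimeError("fit left the data range")
    except RuntimeError:
        peak, sigma = float(vals.mean()), float(vals.std())
        flags["fallback_mean"] = True
    return peak, sigma, flags


def dwell_kinetics(
    events: list[EventRecord], inter_event_intervals_s: np.ndarray
) -> KineticsSummary:
    """Exponential dwell/waiting-time kinetics.

    For exponentially distributed durations the maximum-likelihood
    single-exponential fit is the sample mean, with standard error
    mean/√n; τ_off comes from the event dwell times and τ_on from the
    inter-event waiting times (capture rate = 1/τ_on).
    """
    if len(events) < 20:
        raise InsufficientDataError("need at least 20 events for kinetics")
    dwells = np.array([e.dwell_time for e in events])
    waits = np.asarray(inter_event_intervals_s, dtype=float)
    if waits.size < 2:
        raise InsufficientDataError("need inter-event intervals for tau_on")
    tau_off = float(dwells.mean())
    tau_on = float(waits.mean())
    return KineticsSummary(
        tau_on=tau_on,
        tau_off=tau_off,
        capture_rate=1.0 / tau_on,
        event_count=len(events),
        tau_on_se=tau_on / np.sqrt(waits.size),
        tau_off_se=tau_off / np.sqrt(dwells.size),
    )
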