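"""Within-event multi-level segmentation and open-probability statistics.

A trapped protein visits up to three residence sites, producing discrete
blockade levels L1–L3 (L1 shallowest, i.e. highest residual current).
Levels are defined by *amplitude*: the in-event sample histogram is fit by
a Gaussian mixture with at most ``max_levels`` components, components
closer than twice their width are merged, samples are assigned to the
nearest surviving component, and runs shorter than a minimum dwell are
absorbed into their neighbors.  Labels are assigned by residual-current
rank, so they are stable under subsampling and event reordering.

Open probability of a level is time-weighted: total dwell time in that
level divided by total trapped time, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .events import EventRecord, Trace

__all__ = [
    "LevelSegment",
    "LevelStats",
    "segment_levels",
    "open_probabilities",
    "level_voltage_trend",
]

LEVEL_NAMES = ("L1", "L2", "L3")


@dataclass
class LevelSegment:
    level_id: str  # "L1".."L3"
    start_index: int
    end_index: int  # half-open
    Ires_pct: float  # % of Io
    event_id: int = -1
    single_level_flag: bool = False

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index


@dataclass
class LevelStats:
    """Cohort-level occupancy statistics (time-weighted)."""

    open_probability_pct: dict  # level -> %
    mean_Ires_pct: dict  # level -> %
    mean_duration_s: dict  # level -> s
    n_events: int = 0
    #: standard error of each level's open probability across events
    open_probability_se: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.open_probability_pct.values())
        if self.open_probability_pct and abs(total - 100.0) > 1e-6:
            raise ValueError(f"open probabilities must sum to 100 (got {total})")


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, end, label) runs of a label sequence; end is exclusive."""
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate([[0], change, [labels.size]])
    return [
        (int(bounds[i]), int(bounds[i + 1]), int(labels[bounds[i]]))
        for i in range(bounds.size - 1)
    ]


def _histogram_peaks(x: np.ndarray, max_levels: int) -> np.ndarray:
    """Up to ``max_levels`` amplitude-histogram modes, as mixture seeds.

    Bin width scales with the point-to-point noise (median absolute
    successive difference), so level modes several noise-sigmas apart land
    in separate bins.
    """
    from scipy.signal import find_peaks

    sigma = np.median(np.abs(np.diff(x))) / (1.4826 * np.sqrt(2.0)) * 2.2
    sigma = max(sigma, np.ptp(x) / 200, 1e-9)
    n_bins = max(int(np.ceil(np.ptp(x) / (sigma / 2.0))), 10)
    n_bins = min(n_bins, 400)
    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks, props = find_peaks(counts, height=max(3, 0.002 * x.size), distance=4)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(counts))])
        heights = counts[peaks].astype(float)
    else:
        heights = props["peak_heights"]
    top = peaks[np.argsort(heights)[::-1][:max_levels]]
    return np.sort(centers[top])


def _merge_short_runs(labels: np.ndarray, x: np.ndarray, means: np.ndarray, min_run: int) -> np.ndarray:
    """Absorb runs shorter than ``min_run`` into the nearest-mean neighbor."""
    labels = labels.copy()
    for _ in range(64):  # merging terminates quickly; bound defensively
        runs = _runs(labels)
        if len(runs) <= 1:
            break
        short = [r for r in runs if (r[1] - r[0]) < min_run]
        if not short:
            break
        # merge the shortest run first (order-independent tie-break on index)
        short.sort(key=lambda r: (r[1] - r[0], r[0]))
        s, e, lab = short[0]
        idx = runs.index((s, e, lab))
        neighbors = []
        if idx > 0:
            neighbors.append(runs[idx - 1][2])
        if idx < len(runs) - 1:
            neighbors.append(runs[idx + 1][2])
        seg_mean = x[s:e].mean()
        target = min(neighbors, key=lambda l: abs(means[l] - seg_mean))
        labels[s:e] = target
    return labels


def segment_levels(
    event: EventRecord,
    trace: Trace,
    max_levels: int = 3,
    min_level_dwell: float | None = None,
    rng_seed: int = 0,
) -> list[LevelSegment]:
    """Segment one event into amplitude levels.

    ``min_level_dwell`` is in seconds (default: 5 samples at the trace's
    sampling rate).  If the mixture cannot resolve more than one
    component, a single segment spanning the event is returned with
    ``single_level_flag`` set.
    """
    x = event.samples(trace)
    fs = trace.sampling_rate
    if min_level_dwell is None:
        min_run = 5
    else:
        min_run = max(1, int(round(min_level_dwell * fs)))
    if x.size < 3 * min_run or max_levels == 1:
        return [_single_segment(event, x)]

    # noiseless fast path: few distinct values -> exact assignment
    rounded = np.round(x, 9)
    uniq = np.unique(rounded)
    if uniq.size <= max_levels:
        means = uniq
        labels = np.searchsorted(uniq, rounded)
    else:
        # Initialize the mixture at amplitude-histogram peaks: a minor
        # level (few % occupancy) is a distinct histogram mode but is
        # easily missed by generic initialization when the dominant level
        # holds >90 % of the samples.
        peak_means = _histogram_peaks(x, max_levels)
        gm = GaussianMixture(
            n_components=peak_means.size,
            covariance_type="full",
            means_init=peak_means.reshape(-1, 1),
            random_state=rng_seed,
            reg_covar=1e-6,
        )
        try:
            gm.fit(x.reshape(-1, 1))
        except ValueError:
            return [_single_segment(event, x, flag=True)]
        means = gm.means_.ravel()
        sigmas = np.sqrt(gm.covariances_.ravel())
        # merge components closer than 2 sigma (larger of the pair)
        order = np.argsort(means)
        means, sigmas = means[order], sigmas[order]
        groups: list[list[int]] = [[0]]
        for i in range(1, means.size):
            prev = groups[-1][-1]
            if means[i] - means[prev] < 2.0 * max(sigmas[i], sigmas[prev]):
                groups[-1].append(i)
            else:
                groups.append([i])
        merged_means = np.array([means[g].mean() for g in groups])
        if merged_means.size == 1:
            return [_single_segment(event, x, flag=True)]
        labels = np.argmin(np.abs(x[:, None] - merged_means[None, :]), axis=1)
        means = merged_means

    labels = _merge_short_runs(labels, x, means, min_run)

    used = np.unique(labels)
    # rank surviving levels by residual current, highest current = L1
    seg_means = {int(l): x[labels == l].mean() for l in used}
    rank = sorted(used, key=lambda l: -seg_means[int(l)])
    name_of = {int(l): LEVEL_NAMES[i] if i < len(LEVEL_NAMES) else f"L{i + 1}"
               for i, l in enumerate(rank)}

    segments = []
    for s, e, lab in _runs(labels):
        seg = x[s:e]
        segments.append(
            LevelSegment(
                level_id=name_of[int(lab)],
                start_index=event.start_index + s,
                end_index=event.start_index + e,
                Ires_pct=float(np.median(seg) / event.Io_local * 100.0),
                event_id=event.event_id,
            )
        )
    return segments


def _single_segment(event: EventRecord, x: np.ndarray, flag: bool = False) -> LevelSegment:
    return LevelSegment(
        level_id="L1",
        start_index=event.start_index,
        end_index=event.end_index,
        Ires_pct=float(np.median(x) / event.Io_local * 100.0),
        event_id=event.event_id,
        single_level_flag=flag,
    )


def open_probabilities(
    segments: list[LevelSegment], sampling_rate: float | None = None
) -> LevelStats:
    """Time-weighted level occupancies over an event cohort.

    Per level: open probability = total dwell time in the level / total
    trapped time × 100.  The standard error of each probability is
    estimated from the spread of per-event time fractions.
    """
    if not segments:
        raise ValueError("empty segmentation")
    levels = sorted({s.level_id for s in segments})
    dur = {l: 0 for l in levels}
    ires_w = {l: 0.0 for l in levels}
    per_event: dict[int, dict] = {}
    for s in segments:
        dur[s.level_id] += s.n_samples
        ires_w[s.level_id] += s.Ires_pct * s.n_samples
        ev = per_event.setdefault(s.event_id, {l: 0 for l in levels})
        ev[s.level_id] += s.n_samples
    total = sum(dur.values())
    prob = {l: dur[l] / total * 100.0 for l in levels}
    mean_ires = {l: ires_w[l] / dur[l] if dur[l] else float("nan") for l in levels}
    n_segs = {l: sum(1 for s in segments if s.level_id == l) for l in levels}
    if sampling_rate:
        mean_dur = {l: dur[l] / n_segs[l] / sampling_rate for l in levels}
    else:
        mean_dur = {l: float("nan") for l in levels}

    se = {}
    fracs = {
        l: np.array([ev[l] / sum(ev.values()) * 100.0 for ev in per_event.values()])
        for l in levels
    }
    n_ev = len(per_event)
    for l in levels:
        se[l] = float(fracs[l].std(ddof=1) / np.sqrt(n_ev)) if n_ev > 1 else float("nan")
    return LevelStats(
        open_probability_pct=prob,
        mean_Ires_pct=mean_ires,
        mean_duration_s=mean_dur,
        n_events=n_ev,
        open_probability_se=se,
    )


def level_voltage_trend(cohorts: dict[float, LevelStats]) -> pd.DataFrame:
    """Residual current per level versus applied voltage.

    ``cohorts`` maps voltage (mV) to that cohort's LevelStats.  Returns a
    tidy table (voltage_mv, level, Ires_pct, open_probability_pct) with a
    per-level linear slope column and a monotonicity verdict; a level
    missing at some voltage is recorded as absent (NaN), never
    interpolated.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two voltages")
    levels = sorted({l for st in cohorts.values() for l in st.open_probability_pct})
    rows = []
    for v in sorted(cohorts):
        st = cohorts[v]
        for l in levels:
            rows.append(
                {
                    "voltage_mv": v,
                    "level": l,
                    "Ires_pct": st.mean_Ires_pct.get(l, float("nan")),
                    "open_probability_pct": st.open_probability_pct.get(l, float("nan")),
                }
            )
    df = pd.DataFrame(rows)
    slopes = {}
    trend = {}
    for l in levels:
        sub = df[(df["level"] == l) & df["Ires_pct"].notna()]
        if len(sub) >= 2:
            slope = float(np.polyfit(sub["voltage_mv"], sub["Ires_pct"], 1)[0])
            slopes[l] = slope
            d = np.diff(sub["Ires_pct"].to_numpy())
            trend[l] = (
                "decreasing" if np.all(d < 0)
                else "increasing" if np.all(d > 0)
                else "flat" if np.allclose(d, 0)
                else "mixed"
            )
        else:
            slopes[l] = float("nan")
            trend[l] = "absent"
    df["slope_pct_per_mv"] = df["level"].map(slopes)
    df["trend"] = df["level"].map(trend)
    return df
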