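"""Shared fixtures: synthetic analyte cohorts generated once per session.

The cohorts follow the package's standard study conditions: open-pore
current 500 pA, 2 % broadband white noise, calibrated level-switching
profiles; the free-protein cohort is acquired at 100 kHz (its minor-level
sojourns are sub-millisecond) and the slow-switching complex cohort at
25 kHz.
"""

from __future__ import annotations

import numpy as np
import pytest

from nanofp import profiles
from nanofp.events import detect_events, estimate_open_current
from nanofp.generate import NoiseModel, generate_event_train

IO_PA = 500.0
WHITE_RMS = 10.0  # 2 % of Io


def make_cohort(label: str, fs: float, duration: float, seed: int):
    profile = profiles.make_profile(label, sampling_rate=25_000.0)
    trace, annotation = generate_event_train(
        profile, NoiseModel(white_rms=WHITE_RMS), IO_PA, fs, duration, seed=seed
    )
    Io = estimate_open_current(trace)
    events = detect_events(trace, Io, min_duration=0.01)
    return {
        "profile": profile,
        "trace": trace,
        "annotation": annotation,
        "Io": Io,
        "events": events,
    }


@pytest.fixture(scope="session")
def free_cohort():
    """≥300 free-protein events at 100 kHz."""
    return make_cohort("free_bclxl", fs=100_000.0, duration=130.0, seed=101)


@pytest.fixture(scope="session")
def bak_cohort():
    """≥300 Bak-BH3-complex events at 25 kHz."""
    return make_cohort("bak_bh3_complex", fs=25_000.0, duration=360.0, seed=102)
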