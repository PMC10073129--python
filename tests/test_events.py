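"""Open-current estimation, event detection, blockade and dwell statistics."""

import numpy as np
import pytest

from nanofp import profiles
from nanofp.events import (
    EstimationError,
    EventRecord,
    InsufficientDataError,
    Trace,
    blockade_statistics,
    detect_events,
    dwell_kinetics,
    estimate_open_current,
    inter_event_intervals,
)
from nanofp.generate import NoiseModel, generate_event_train


class TestEstimateOpenCurrent:
    def test_constant_trace(self):
        tr = Trace(np.full(1000, 500.0), sampling_rate=1000.0)
        assert estimate_open_current(tr) == pytest.approx(500.0)

    def test_synthetic_trace_with_events(self, free_cohort):
        assert free_cohort["Io"] == pytest.approx(500.0, abs=2.0)

    def test_no_baseline_population_raises(self):
        # continuously drifting signal: no resolvable open-pore mode
        rng = np.random.default_rng(0)
        x = np.linspace(100.0, 400.0, 20_000) + rng.standard_normal(20_000)
        with pytest.raises(EstimationError):
            estimate_open_current(Trace(x, sampling_rate=10_000.0))


class TestDetectEvents:
    def test_noiseless_boundaries_sample_exact(self):
        profile = profiles.make_profile("bak_bh3_complex", sampling_rate=25_000.0)
        trace, ann = generate_event_train(
            profile, NoiseModel(white_rms=0.0), 500.0, 25_000.0, 30.0, seed=20
        )
        events = detect_events(trace, 500.0)
        assert [(e.start_index, e.end_index) for e in events] == [
            (a.start_index, a.end_index) for a in ann.events
        ]

    def test_noisy_recovery_rate_and_boundary_error(self, free_cohort):
        ann, events = free_cohort["annotation"], free_cohort["events"]
        fs = free_cohort["trace"].sampling_rate
        true_bounds = [(a.start_index, a.end_index) for a in ann.events]
        det_starts = np.array([e.start_index for e in events])
        recovered = 0
        errors = []
        for s, e in true_bounds:
            if (e - s) / fs < 0.01:  # below the detection minimum duration
                continue
            k = np.argmin(np.abs(det_starts - s))
            if abs(det_starts[k] - s) <= fs * 0.005:
                recovered += 1
                errors.append(abs(det_starts[k] - s) / fs)
        considered = sum(1 for s, e in true_bounds if (e - s) / fs >= 0.01)
        assert recovered / considered >= 0.99
        assert np.median(errors) <= 1e-3

    def test_flat_trace_has_no_events(self):
        tr = Trace(np.full(5000, 500.0), sampling_rate=1000.0)
        assert detect_events(tr, 500.0) == []

    def test_events_are_ordered_and_disjoint(self, bak_cohort):
        events = bak_cohort["events"]
        assert len(events) >= 300
        for a, b in zip(events[:-1], events[1:]):
            assert a.end_index <= b.start_index

    def test_idempotent_on_same_trace(self, bak_cohort):
        tr, Io = bak_cohort["trace"], bak_cohort["Io"]
        again = detect_events(tr, Io, min_duration=0.01)
        assert [(e.start_index, e.end_index) for e in again] == [
            (e.start_index, e.end_index) for e in bak_cohort["events"]
        ]

    def test_nonpositive_io_rejected(self):
        tr = Trace(np.zeros(100), sampling_rate=1000.0)
        with pytest.raises(ValueError):
            detect_events(tr, 0.0)


def _records(blockades, Io=500.0, dwell=0.01):
    return [
        EventRecord(
            start_index=i * 100,
            end_index=i * 100 + 50,
            Io_local=Io,
            mean_blockade_dIoverIo=b,
            median_residual_Ires=100.0 - b,
            dwell_time=dwell,
            event_id=i,
        )
        for i, b in enumerate(blockades)
    ]


class TestBlockadeStatistics:
    def test_uniform_cohort_arithmetic(self):
        # Io = 500 pA, residual 174 pA -> blockade 65.2 %
        rng = np.random.default_rng(1)
        vals = 65.2 + 0.3 * rng.standard_normal(200)
        peak, sigma, flags = blockade_statistics(_records(vals))
        assert peak == pytest.approx(65.2, abs=0.1)
        assert not flags["bimodal"]

    def test_free_protein_cohort_peak(self, free_cohort):
        events = free_cohort["events"]
        peak, _, _ = blockade_statistics(events)
        assert peak == pytest.approx(65.2, abs=0.5)

    def test_bimodal_cohort_flagged(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate(
            [50.0 + 0.5 * rng.standard_normal(100), 70.0 + 0.5 * rng.standard_normal(100)]
        )
        _, _, flags = blockade_statistics(_records(vals))
        assert flags["bimodal"]

    def test_too_few_events_rejected(self):
        with pytest.raises(InsufficientDataError):
            blockade_statistics(_records([65.0] * 5))


class TestDwellKinetics:
    def test_exponential_mle_recovers_tau(self):
        rng = np.random.default_rng(3)
        dwells = rng.exponential(0.010, size=500)
        waits = rng.exponential(0.050, size=499)
        events = _records(np.full(500, 60.0))
        for e, d in zip(events, dwells):
            e.dwell_time = d
        k = dwell_kinetics(events, waits)
        assert abs(k.tau_off - 0.010) < 2.0 * k.tau_off_se
        assert abs(k.tau_on - 0.050) < 3.0 * k.tau_on_se
        assert k.capture_rate == pytest.approx(1.0 / k.tau_on)

    def test_doubling_capture_rate_doubles_recovered_rate(self):
        rng = np.random.default_rng(4)
        events = _records(np.full(300, 60.0))
        k1 = dwell_kinetics(events, rng.exponential(0.1, 300))
        k2 = dwell_kinetics(events, rng.exponential(0.05, 300))
        assert k2.capture_rate / k1.capture_rate == pytest.approx(2.0, rel=0.2)

    def test_single_event_rejected(self):
        with pytest.raises(InsufficientDataError):
            dwell_kinetics(_records([60.0]), np.array([]))


def test_inter_event_intervals_basic():
    events = _records([60.0, 60.0, 60.0])
    # events at [0,50), [100,150), [200,250) with fs baked into records
    waits = inter_event_intervals(events, 1000.0)
    assert np.allclose(waits, 0.05)
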