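"""Multi-level segmentation and open-probability statistics."""

import numpy as np
import pytest

from nanofp.events import EventRecord, Trace
from nanofp.levels import (
    LevelSegment,
    level_voltage_trend,
    open_probabilities,
    segment_levels,
)


def _event_over(x, fs=10_000.0, Io=500.0):
    trace = Trace(x, sampling_rate=fs)
    ev = EventRecord(
        start_index=0,
        end_index=x.size,
        Io_local=Io,
        mean_blockade_dIoverIo=float((Io - np.median(x)) / Io * 100.0),
        median_residual_Ires=float(np.median(x) / Io * 100.0),
        dwell_time=x.size / fs,
        event_id=0,
    )
    return ev, trace


class TestSegmentLevels:
    def test_noiseless_three_step_event_is_exact(self):
        x = np.concatenate([np.full(300, 364.0), np.full(500, 174.0), np.full(200, 125.0)])
        ev, trace = _event_over(x)
        segs = segment_levels(ev, trace)
        assert [(s.level_id, s.start_index, s.end_index) for s in segs] == [
            ("L1", 0, 300),
            ("L2", 300, 800),
            ("L3", 800, 1000),
        ]
        assert segs[0].Ires_pct == pytest.approx(364.0 / 500.0 * 100.0)

    def test_max_levels_one_gives_single_segment(self):
        x = np.concatenate([np.full(300, 364.0), np.full(500, 174.0)])
        ev, trace = _event_over(x)
        segs = segment_levels(ev, trace, max_levels=1)
        assert len(segs) == 1
        assert (segs[0].start_index, segs[0].end_index) == (0, 800)

    def test_noisy_occupancy_recovery_5_90_5(self):
        # alternating visits: 5 % L1, 90 % L2, 5 % L3 with 2 % of Io noise
        rng = np.random.default_rng(7)
        chunks = []
        pattern = [(364.0, 50), (174.0, 450), (125.0, 50), (174.0, 450)]
        for _ in range(10):
            for level, n in pattern:
                chunks.append(np.full(n, level))
        x = np.concatenate(chunks) + 10.0 * rng.standard_normal(10 * 1000)
        ev, trace = _event_over(x)
        segs = segment_levels(ev, trace)
        stats = open_probabilities(segs, trace.sampling_rate)
        assert stats.open_probability_pct["L1"] == pytest.approx(5.0, abs=1.0)
        assert stats.open_probability_pct["L2"] == pytest.approx(90.0, abs=1.5)
        assert stats.open_probability_pct["L3"] == pytest.approx(5.0, abs=1.0)

    def test_short_runs_merged_into_neighbors(self):
        x = np.concatenate(
            [np.full(400, 364.0), np.full(2, 125.0), np.full(400, 364.0),
             np.full(300, 174.0)]
        )
        ev, trace = _event_over(x)
        segs = segment_levels(ev, trace, min_level_dwell=5 / 10_000.0)
        assert [s.level_id for s in segs] == ["L1", "L2"]
        assert segs[0].end_index == 802


class TestOpenProbabilities:
    @staticmethod
    def _segs(durations, event_id=0):
        out = []
        pos = 0
        for (lvl, n, ires) in durations:
            out.append(LevelSegment(lvl, pos, pos + n, ires, event_id=event_id))
            pos += n
        return out

    def test_durations_5_90_5(self):
        segs = self._segs([("L1", 50, 72.8), ("L2", 900, 34.8), ("L3", 50, 25.0)])
        stats = open_probabilities(segs, 10_000.0)
        assert stats.open_probability_pct == {"L1": 5.0, "L2": 90.0, "L3": 5.0}

    def test_probabilities_sum_to_100(self, bak_cohort):
        segs = []
        for ev in bak_cohort["events"][:50]:
            segs.extend(segment_levels(ev, bak_cohort["trace"]))
        stats = open_probabilities(segs, bak_cohort["trace"].sampling_rate)
        assert sum(stats.open_probability_pct.values()) == pytest.approx(100.0)

    def test_cohort_stats_invariant_under_event_order(self):
        a = self._segs([("L1", 100, 72.8), ("L2", 300, 34.8)], event_id=0)
        b = self._segs([("L2", 500, 34.8), ("L3", 100, 25.0)], event_id=1)
        fwd = open_probabilities(a + b, 1000.0)
        rev = open_probabilities(b + a, 1000.0)
        assert fwd.open_probability_pct == rev.open_probability_pct

    def test_empty_segmentation_rejected(self):
        with pytest.raises(ValueError):
            open_probabilities([], 1000.0)


class TestVoltageTrend:
    @staticmethod
    def _stats(ires_by_level):
        from nanofp.levels import LevelStats

        n = len(ires_by_level)
        return LevelStats(
            open_probability_pct={l: 100.0 / n for l in ires_by_level},
            mean_Ires_pct=dict(ires_by_level),
            mean_duration_s={l: 0.01 for l in ires_by_level},
            n_events=100,
        )

    def test_decreasing_residual_with_voltage_reported(self):
        cohorts = {
            60.0: self._stats({"L1": 78.0, "L2": 40.0}),
            80.0: self._stats({"L1": 75.0, "L2": 37.0}),
            100.0: self._stats({"L1": 72.8, "L2": 34.8}),
        }
        df = level_voltage_trend(cohorts)
        assert set(df[df.level == "L1"].trend) == {"decreasing"}
        assert df[df.level == "L2"].slope_pct_per_mv.iloc[0] < 0

    def test_identical_cohorts_zero_trend(self):
        s = self._stats({"L1": 70.0})
        df = level_voltage_trend({60.0: s, 100.0: s})
        assert set(df.trend) == {"flat"}

    def test_missing_level_recorded_absent(self):
        cohorts = {
            60.0: self._stats({"L1": 78.0, "L2": 40.0}),
            100.0: self._stats({"L1": 72.8}),
        }
        df = level_voltage_trend(cohorts)
        l2 = df[(df.level == "L2") & (df.voltage_mv == 100.0)]
        assert np.isnan(l2.Ires_pct.iloc[0])

    def test_single_voltage_rejected(self):
        with pytest.raises(ValueError):
            level_voltage_trend({100.0: self._stats({"L1": 70.0})})
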