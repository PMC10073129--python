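"""Level-switching generator: CTMC engine, event trains, titrations,
competition time-courses, and the position→current map."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from nanofp import ctmc, profiles
from nanofp.generate import (
    DEFAULT_CURRENT_MAP,
    AnalyteProfile,
    CurrentMap,
    NoiseModel,
    generate_competition_timecourse,
    generate_event_train,
    generate_titration,
    position_to_current,
)


class TestCtmc:
    def test_star_rate_matrix_has_requested_stationary_law(self):
        pi = np.array([0.0498, 0.9125, 0.0377])
        Q = ctmc.star_rate_matrix(pi, 300.0)
        assert np.allclose(ctmc.stationary_distribution(Q), pi, atol=1e-12)

    def test_psd_mode_weights_sum_to_variance(self):
        pi = np.array([0.4213, 0.5771, 0.0016])
        Q = ctmc.star_rate_matrix(pi, 100.0)
        levels = np.array([364.0, 174.0, 125.0])
        _, c = ctmc.psd_modes(Q, levels)
        mu = pi @ levels
        assert c.sum() == pytest.approx(pi @ (levels - mu) ** 2, rel=1e-10)

    def test_band_variance_converges_to_total(self):
        Q = ctmc.star_rate_matrix(np.array([0.3, 0.7]), 50.0)
        levels = np.array([1.0, 0.0])
        total = ctmc.band_variance(Q, levels, 0.0, 1e9)
        _, c = ctmc.psd_modes(Q, levels)
        assert total == pytest.approx(c.sum(), rel=1e-4)

    def test_sampled_path_occupancies_match_stationary(self):
        pi = np.array([0.25, 0.75])
        Q = ctmc.star_rate_matrix(pi, 200.0)
        rng = np.random.default_rng(3)
        states, times = ctmc.sample_path(Q, 200.0, rng)
        bounds = np.concatenate([times, [200.0]])
        dur = np.diff(bounds)
        occ0 = dur[states == 0].sum() / 200.0
        assert occ0 == pytest.approx(0.25, abs=0.02)


class TestPositionToCurrent:
    def test_residence_site_anchors(self):
        Io = DEFAULT_CURRENT_MAP.open_pore_current_Io
        assert position_to_current(np.array([4.0]))[0] == pytest.approx(0.35 * Io)
        assert position_to_current(np.array([10.0]))[0] == pytest.approx(0.73 * Io)

    def test_post_escape_emits_open_pore_current(self):
        out = position_to_current(np.array([4.0, np.nan, np.nan]))
        assert out[1] == out[2] == DEFAULT_CURRENT_MAP.open_pore_current_Io

    def test_clamped_outside_anchor_range(self):
        lo = position_to_current(np.array([0.5]))[0]
        assert lo == position_to_current(np.array([4.0]))[0]

    def test_non_monotone_map_rejected(self):
        with pytest.raises(ValueError):
            CurrentMap(anchor_points=((4.0, 73.0), (10.0, 35.0)))


def _single_level_profile(capture_rate=5.0, tau_off=0.1):
    return AnalyteProfile(
        label="one_level",
        level_residual_fractions=(35.0,),
        level_occupancies=(1.0,),
        level_switch_rates=np.zeros((1, 1)),
        mean_dwell_tau_off=tau_off,
        capture_rate_1_over_tau_on=capture_rate,
    )


class TestGenerateEventTrain:
    def test_single_level_rectangular_pulses(self):
        trace, ann = generate_event_train(
            _single_level_profile(), NoiseModel(white_rms=0.0), 500.0, 10_000.0, 5.0, seed=1
        )
        assert len(ann.events) > 0
        in_event = np.zeros(trace.n_samples, dtype=bool)
        for ev in ann.events:
            in_event[ev.start_index : ev.end_index] = True
            assert np.allclose(trace.current_pA[ev.start_index : ev.end_index], 175.0)
        assert np.allclose(trace.current_pA[~in_event], 500.0)

    def test_annotation_consistent_with_noiseless_trace(self):
        profile = profiles.make_profile("bak_bh3_complex", sampling_rate=25_000.0)
        trace, ann = generate_event_train(
            profile, NoiseModel(white_rms=0.0), 500.0, 25_000.0, 20.0, seed=2
        )
        level_I = profile.level_currents(500.0)
        for ev in ann.events:
            for seg in ev.segments:
                seg_vals = trace.current_pA[seg.start_index : seg.end_index]
                assert np.allclose(seg_vals, level_I[seg.level_index])

    def test_level_occupancies_match_configuration(self):
        profile = profiles.make_profile("free_bclxl", sampling_rate=25_000.0)
        trace, ann = generate_event_train(
            profile, NoiseModel(white_rms=0.0), 500.0, 50_000.0, 60.0, seed=3
        )
        dur = np.zeros(3)
        for ev in ann.events:
            for seg in ev.segments:
                dur[seg.level_index] += seg.end_index - seg.start_index
        occ = dur / dur.sum()
        want = np.array(profile.level_occupancies)
        # binomial-scale tolerance on the dominant level
        assert np.allclose(occ, want, atol=0.015)

    def test_mean_event_duration_matches_tau_off(self):
        profile = _single_level_profile(capture_rate=20.0, tau_off=0.05)
        trace, ann = generate_event_train(
            profile, NoiseModel(white_rms=0.0), 500.0, 10_000.0, 60.0, seed=4
        )
        # drop the possibly truncated last event
        durs = np.array(
            [(e.end_index - e.start_index) / 10_000.0 for e in ann.events[:-1]]
        )
        se = durs.std(ddof=1) / np.sqrt(durs.size)
        assert abs(durs.mean() - 0.05) < 3.0 * se

    def test_bit_reproducible_under_seed(self):
        profile = profiles.make_profile("free_bclxl", sampling_rate=25_000.0)
        a, _ = generate_event_train(profile, NoiseModel(), 500.0, 25_000.0, 3.0, seed=5)
        b, _ = generate_event_train(profile, NoiseModel(), 500.0, 25_000.0, 3.0, seed=5)
        assert np.array_equal(a.current_pA, b.current_pA)

    def test_inconsistent_occupancies_and_rates_rejected(self):
        Q = ctmc.star_rate_matrix(np.array([0.5, 0.5]), 100.0)
        with pytest.raises(ValueError, match="stationary"):
            AnalyteProfile(
                label="bad",
                level_residual_fractions=(70.0, 35.0),
                level_occupancies=(0.9, 0.1),
                level_switch_rates=Q,
                mean_dwell_tau_off=0.1,
                capture_rate_1_over_tau_on=1.0,
            )


class TestTitration:
    def test_half_saturation_bound_fraction(self):
        t = generate_titration(19.0, 1.0, [19.0], events_per_point=200_000, seed=6)
        assert t["F_c_pct"].iloc[0] == pytest.approx(50.0, abs=0.5)

    def test_saturation_limit(self):
        t = generate_titration(19.0, 0.9, [1e9], events_per_point=200_000, seed=7)
        assert t["F_c_pct"].iloc[0] == pytest.approx(90.0, abs=0.5)

    @pytest.mark.parametrize("n_events", [100, 1000, 10000])
    def test_empirical_curve_within_binomial_ci(self, n_events):
        KD, Bmax = 38.0, 1.0
        concs = [5.0, 38.0, 200.0]
        t = generate_titration(KD, Bmax, concs, n_events, seed=8)
        p = Bmax * np.array(concs) / (KD + np.array(concs))
        se = np.sqrt(p * (1 - p) / n_events) * 100.0
        assert np.all(np.abs(t["F_c_pct"] - p * 100.0) < 4.0 * se)

    def test_probability_above_one_capped_or_strict(self):
        t = generate_titration(19.0, 1.11, [1e6], events_per_point=100, seed=9)
        assert t["F_c_pct"].iloc[0] == 100.0
        with pytest.raises(ValueError, match="exceeds 1"):
            generate_titration(19.0, 1.11, [1e6], 100, seed=9, strict=True)


class TestCompetition:
    def test_zero_rate_keeps_initial_population(self):
        t = generate_competition_timecourse("a", "b", 0.0, [0.0, 100.0, 1e4], 500, seed=10)
        assert np.all(t["fraction_displaced_pct"] == 0.0)

    def test_half_life(self):
        k = 0.01
        t = generate_competition_timecourse(
            "a", "b", k, [np.log(2) / k], 100_000, seed=11
        )
        assert t["fraction_displaced_pct"].iloc[0] == pytest.approx(50.0, abs=0.6)

    def test_rate_recovered_by_exponential_fit(self):
        k = 0.002
        windows = [0.0, 300.0, 600.0, 1200.0, 2400.0]
        t = generate_competition_timecourse("a", "b", k, windows, 2000, seed=12)
        popt, _ = curve_fit(
            lambda t_, k_: 100.0 * (1.0 - np.exp(-k_ * t_)),
            t["time_s"],
            t["fraction_displaced_pct"],
            p0=[0.001],
        )
        assert popt[0] == pytest.approx(k, rel=0.1)
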