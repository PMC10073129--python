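"""2D fingerprinting, population assignment, and one-site binding fits."""

import numpy as np
import pandas as pd
import pytest

from nanofp.fingerprint import (
    FingerprintPoint,
    IllConditionedFitError,
    TitrationSeries,
    bound_fraction,
    classify,
    fingerprint_events,
    fit_binding,
    fit_populations,
    one_site_binding,
    population_timecourse,
)
from nanofp.generate import generate_titration


def _cloud(n, mean, sd, label_time=0.0, seed=0):
    rng = np.random.default_rng(seed)
    return [
        FingerprintPoint(
            event_id=i,
            dIoverIo_pct=float(mean[0] + sd[0] * rng.standard_normal()),
            IN_pA=float(mean[1] + sd[1] * rng.standard_normal()),
            wall_time_s=label_time + i * 0.1,
        )
        for i in range(n)
    ]


class TestFingerprintEvents:
    def test_cohort_coordinates_match_analyte(self, free_cohort):
        pts = fingerprint_events(free_cohort["events"], free_cohort["trace"])
        dI = np.array([p.dIoverIo_pct for p in pts])
        assert np.mean(dI) == pytest.approx(65.2, abs=0.5)

    def test_self_normalized_cohort_centers_at_unity(self, free_cohort):
        pts = fingerprint_events(free_cohort["events"], free_cohort["trace"])
        ref = (
            float(np.mean([p.dIoverIo_pct for p in pts])),
            float(np.mean([p.IN_pA for p in pts])),
        )
        pts_n = fingerprint_events(free_cohort["events"], free_cohort["trace"], reference=ref)
        assert np.mean([p.norm_dI for p in pts_n]) == pytest.approx(1.0, abs=0.01)
        assert np.mean([p.norm_IN for p in pts_n]) == pytest.approx(1.0, abs=0.05)

    def test_invalid_reference_rejected(self, free_cohort):
        with pytest.raises(ValueError):
            fingerprint_events(
                free_cohort["events"][:5], free_cohort["trace"], reference=(0.0, 1.0)
            )


class TestPopulations:
    def test_two_separated_clusters_classified(self):
        a = _cloud(200, (65.2, 16.3), (0.5, 2.0), seed=1)
        b = _cloud(200, (63.0, 78.9), (0.8, 3.5), seed=2)
        model = fit_populations(a + b, K=2, seed=0)
        classify(a + b, model)
        # component order is arbitrary; demand a consistent split
        la = {p.assigned_population for p in a}
        lb = {p.assigned_population for p in b}
        acc_a = max(sum(p.assigned_population == l for p in a) for l in la) / len(a)
        acc_b = max(sum(p.assigned_population == l for p in b) for l in lb) / len(b)
        assert acc_a >= 0.99 and acc_b >= 0.99

    def test_k1_assigns_single_label(self):
        pts = _cloud(50, (65.0, 16.0), (1.0, 2.0), seed=3)
        model = fit_populations(pts, K=1, seed=0)
        classify(pts, model)
        assert {p.assigned_population for p in pts} == {"P1"}

    def test_label_permutation_leaves_partition_unchanged(self):
        pts = _cloud(100, (65.0, 16.0), (1.0, 2.0), seed=4) + _cloud(
            100, (50.0, 40.0), (1.0, 2.0), seed=5
        )
        model = fit_populations(pts, K=2, seed=0)
        classify(pts, model, labels=["x", "y"])
        part1 = [p.assigned_population == "x" for p in pts]
        classify(pts, model, labels=["y", "x"])
        part2 = [p.assigned_population == "y" for p in pts]
        assert part1 == part2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_populations(_cloud(15, (65.0, 16.0), (1.0, 2.0)), K=2)

    def test_accuracy_monotone_in_separation(self):
        accs = []
        for gap in (2.0, 6.0, 20.0):
            a = _cloud(150, (65.0, 16.0), (1.0, 2.0), seed=6)
            b = _cloud(150, (65.0, 16.0 + gap), (1.0, 2.0), seed=7)
            model = fit_populations(a + b, K=2, seed=0)
            classify(a + b, model)
            acc = max(
                sum(p.assigned_population == l for p in a) for l in {"P1", "P2"}
            ) / len(a)
            accs.append(acc)
        assert accs[0] <= accs[1] + 0.02 and accs[1] <= accs[2] + 0.02


class TestTimecourse:
    def test_window_fractions_sum_to_100(self):
        pts = _cloud(60, (65.0, 16.0), (1.0, 2.0), seed=8)
        for i, p in enumerate(pts):
            p.assigned_population = "P1" if i % 3 else "P2"
        df = population_timecourse(pts, window_s=2.0)
        sums = df[[c for c in df.columns if c.startswith("pct_")]].sum(axis=1)
        assert np.allclose(sums[df.n_events > 0], 100.0)

    def test_constant_population_stays_constant(self):
        pts = _cloud(60, (65.0, 16.0), (1.0, 2.0), seed=9)
        for p in pts:
            p.assigned_population = "P1"
        df = population_timecourse(pts, window_s=1.0)
        assert np.allclose(df[df.n_events > 0]["pct_P1"], 100.0)


class TestBoundFraction:
    @pytest.mark.parametrize(
        "nc,nt,expect", [(50, 100, 50.0), (0, 7, 0.0), (466, 466, 100.0)]
    )
    def test_exact_ratio(self, nc, nt, expect):
        assert bound_fraction(nc, nt) == expect

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            bound_fraction(5, 0)
        with pytest.raises(ValueError):
            bound_fraction(11, 10)


def _series_from_curve(KD, Bmax, concs):
    y = one_site_binding(np.asarray(concs, dtype=float), Bmax, KD)
    n_total = 10**7
    n_comp = np.round(y * n_total).astype(int)
    return TitrationSeries(
        pd.DataFrame(
            {
                "concentration_nM": concs,
                "N_comp": n_comp,
                "N_total": n_total,
                "F_c_pct": n_comp / n_total * 100.0,
            }
        )
    )


class TestFitBinding:
    def test_noise_free_curve_recovered_exactly(self):
        concs = [2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0]
        fit = fit_binding(_series_from_curve(38.0, 0.95, concs))
        assert fit.K_D == pytest.approx(38.0, rel=1e-4)
        assert fit.B_max == pytest.approx(0.95, rel=1e-4)

    def test_binomial_titration_recovers_kd_within_reported_ci(self):
        table = generate_titration(
            19.0, 1.11, list(np.geomspace(1.0, 500.0, 9)), 300, seed=30
        )
        fit = fit_binding(TitrationSeries(table))
        assert abs(fit.K_D - 19.0) <= 4.0

    def test_fewer_events_widen_confidence_interval(self):
        concs = list(np.geomspace(1.0, 500.0, 9))
        wide = fit_binding(
            TitrationSeries(generate_titration(38.0, 1.0, concs, 50, seed=31)),
            weighted=True,
        )
        narrow = fit_binding(
            TitrationSeries(generate_titration(38.0, 1.0, concs, 2000, seed=31)),
            weighted=True,
        )
        assert (wide.K_D_ci95[1] - wide.K_D_ci95[0]) > (
            narrow.K_D_ci95[1] - narrow.K_D_ci95[0]
        )

    def test_saturated_titration_rejected(self):
        concs = [1000.0, 2000.0, 4000.0, 8000.0]
        with pytest.raises(IllConditionedFitError):
            fit_binding(_series_from_curve(1.0, 1.0, concs))

    def test_ci_brackets_estimate(self):
        table = generate_titration(38.0, 1.0, list(np.geomspace(1, 500, 8)), 500, seed=32)
        fit = fit_binding(TitrationSeries(table))
        assert fit.K_D_ci95[0] <= fit.K_D <= fit.K_D_ci95[1]
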