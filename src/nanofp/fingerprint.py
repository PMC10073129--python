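"""2D blockade-vs-noise fingerprinting and equilibrium binding analysis.

Each trapping event maps to a point (ΔI/I_o %, I_N pA at the 100 Hz
refilter).  Ligand binding shifts this fingerprint: complexes carry higher
low-frequency noise and (for some drugs) a different dominant blockade, so
cohorts of free protein and of each complex form separated clusters.  A
2D Gaussian mixture fitted over pooled points gives a reproducible
population-assignment rule (maximum posterior); population fractions per
time window track mixture screening and competitive displacement.

Equilibrium binding: the bound fraction F_c = N_comp/N_total × 100 at each
ligand concentration X follows the one-site curve

    Y = B_max · X / (K_D + X),

fit by unweighted nonlinear least squares (an optional binomial-variance
weighting flag exists); K_D and B_max are reported with 95 % confidence
intervals from the fit covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

from .events import EventRecord, Trace
from .noise import IN_vs_cutoff, MIN_SEGMENT_SAMPLES

__all__ = [
    "FingerprintPoint",
    "PopulationModel",
    "TitrationSeries",
    "BindingFit",
    "IllConditionedFitError",
    "fingerprint_events",
    "fit_populations",
    "classify",
    "population_timecourse",
    "bound_fraction",
    "fit_binding",
    "one_site_binding",
]


class IllConditionedFitError(RuntimeError):
    """The titration carries no usable curvature for a K_D estimate."""


@dataclass
class FingerprintPoint:
    event_id: int
    dIoverIo_pct: float
    IN_pA: float
    wall_time_s: float
    assigned_population: str | None = None
    norm_dI: float | None = None
    norm_IN: float | None = None


@dataclass
class PopulationModel:
    means: np.ndarray  # (K, 2)
    covariances: np.ndarray  # (K, 2, 2)
    weights: np.ndarray  # (K,)
    log_likelihood: float

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("mixture weights must sum to 1")
        for c in self.covariances:
            if np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError("covariances must be positive definite")

    @property
    def n_components(self) -> int:
        return self.weights.size


@dataclass
class TitrationSeries:
    """Per-concentration complexed/total event counts."""

    table: pd.DataFrame  # concentration_nM, N_comp, N_total, F_c_pct

    def __post_init__(self) -> None:
        t = self.table
        if np.any(t["N_comp"] > t["N_total"]) or np.any(t["N_comp"] < 0):
            raise ValueError("need 0 <= N_comp <= N_total")
        expect = t["N_comp"] / t["N_total"] * 100.0
        if not np.allclose(t["F_c_pct"], expect):
            raise ValueError("F_c_pct must equal 100*N_comp/N_total")


@dataclass
class BindingFit:
    K_D: float  # nM
    B_max: float
    K_D_ci95: tuple[float, float]
    B_max_ci95: tuple[float, float]
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.K_D <= 0:
            raise ValueError("K_D must be positive")
        if not (self.K_D_ci95[0] <= self.K_D <= self.K_D_ci95[1]):
            raise ValueError("CI must bracket the K_D estimate")


def fingerprint_events(
    events: list[EventRecord],
    trace: Trace,
    cutoff_hz: float = 100.0,
    reference: tuple[float, float] | None = None,
) -> list[FingerprintPoint]:
    """One (ΔI/I_o, I_N) point per event.

    ``reference`` is the (ΔI/I_o, I_N) of a free-protein cohort (its
    Gaussian-fit means); when given, normalized coordinates are attached.
    Events too short for a 100 Hz periodogram are skipped.
    """
    pts = []
    for ev in events:
        if ev.n_samples < MIN_SEGMENT_SAMPLES:
            continue
        i_n = IN_vs_cutoff(ev, trace, (cutoff_hz,))[0].I_N
        p = FingerprintPoint(
            event_id=ev.event_id,
            dIoverIo_pct=ev.mean_blockade_dIoverIo,
            IN_pA=i_n,
            wall_time_s=ev.start_index / trace.sampling_rate,
        )
        if reference is not None:
            ref_dI, ref_IN = reference
            if ref_dI <= 0 or ref_IN <= 0:
                raise ValueError("normalization reference must be positive")
            p.norm_dI = p.dIoverIo_pct / ref_dI
            p.norm_IN = p.IN_pA / ref_IN
        pts.append(p)
    return pts


def _points_matrix(points: list[FingerprintPoint]) -> np.ndarray:
    return np.array([[p.dIoverIo_pct, p.IN_pA] for p in points])


def fit_populations(points: list[FingerprintPoint], K: int, seed: int = 0) -> PopulationModel:
    """K-component full-covariance 2D Gaussian mixture over the points."""
    if len(points) < 10 * K:
        raise ValueError(f"need at least {10 * K} points for K={K}")
    X = _points_matrix(points)
    gm = GaussianMixture(
        n_components=K, covariance_type="full", n_init=5, random_state=seed
    )
    gm.fit(X)
    if not gm.converged_:
        raise RuntimeError(
            f"mixture fit did not converge (lower bound {gm.lower_bound_:.3g})"
        )
    return PopulationModel(
        means=gm.means_,
        covariances=gm.covariances_,
        weights=gm.weights_,
        log_likelihood=float(gm.lower_bound_ * len(points)),
    )


def classify(
    points: list[FingerprintPoint],
    model: PopulationModel,
    labels: list[str] | None = None,
) -> list[FingerprintPoint]:
    """Maximum-posterior population assignment (ties → lowest index).

    ``labels`` names the components (default "P1".."PK"); points are
    annotated in place and returned.
    """
    if labels is None:
        labels = [f"P{k + 1}" for k in range(model.n_components)]
    X = _points_matrix(points)
    log_post = np.empty((X.shape[0], model.n_components))
    for k in range(model.n_components):
        rv = stats.multivariate_normal(model.means[k], model.covariances[k])
        log_post[:, k] = np.log(model.weights[k]) + rv.logpdf(X)
    # argmax returns the lowest index on ties
    best = np.argmax(np.round(log_post, 12), axis=1)
    for p, k in zip(points, best):
        p.assigned_population = labels[int(k)]
    return points


def population_timecourse(points: list[FingerprintPoint], window_s: float) -> pd.DataFrame:
    """Per-window population percentages (summing to 100 per window).

    Windows with no events are recorded with NaN fractions, never
    interpolated.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    if any(p.assigned_population is None for p in points):
        raise ValueError("points must be classified first")
    labels = sorted({p.assigned_population for p in points})
    t_max = max(p.wall_time_s for p in points)
    n_win = int(np.floor(t_max / window_s)) + 1
    rows = []
    for w in range(n_win):
        in_win = [p for p in points if w * window_s <= p.wall_time_s < (w + 1) * window_s]
        row = {"window_start_s": w * window_s, "n_events": len(in_win)}
        for lab in labels:
            if in_win:
                row[f"pct_{lab}"] = 100.0 * sum(
                    p.assigned_population == lab for p in in_win
                ) / len(in_win)
            else:
                row[f"pct_{lab}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def bound_fraction(N_comp: int, N_total: int) -> float:
    """F_c = N_comp / N_total × 100, %."""
    if N_total <= 0:
        raise ValueError("N_total must be positive")
    if not (0 <= N_comp <= N_total):
        raise ValueError("need 0 <= N_comp <= N_total")
    return N_comp / N_total * 100.0


def one_site_binding(X, Bmax, KD):
    """Y = B_max X / (K_D + X); X in nM, Y a fraction."""
    return Bmax * X / (KD + X)


def fit_binding(series: TitrationSeries, weighted: bool = False) -> BindingFit:
    """Nonlinear least-squares fit of the one-site curve to F_c/100 vs X.

    Unweighted by default; ``weighted=True`` applies binomial standard
    deviations √(p(1-p)/N) as sigma.  95 % confidence intervals use the
    t-distribution on the fit covariance.
    """
    t = series.table
    X = t["concentration_nM"].to_numpy(dtype=float)
    y = t["F_c_pct"].to_numpy(dtype=float) / 100.0
    if X.size < 4:
        raise IllConditionedFitError("need at least 4 concentrations")
    if y.max() - y.min() < 0.05:
        raise IllConditionedFitError(
            "titration has no curvature (all saturated or all near zero)"
        )
    sigma = None
    if weighted:
        p = np.clip(y, 1e-3, 1 - 1e-3)
        sigma = np.sqrt(p * (1 - p) / t["N_total"].to_numpy())
    half = 0.5 * (y.min() + y.max())
    kd0 = float(X[np.argmin(np.abs(y - half))])
    popt, pcov = curve_fit(
        one_site_binding,
        X,
        y,
        p0=[max(y.max(), 0.1), max(kd0, X.min())],
        sigma=sigma,
        absolute_sigma=weighted,
        maxfev=10000,
    )
    bmax, kd = popt
    if kd <= 0 or not np.all(np.isfinite(pcov)):
        raise IllConditionedFitError("fit covariance is singular")
    dof = max(X.size - 2, 1)
    tval = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.diag(pcov))
    resid = y - one_site_binding(X, *popt)
    return BindingFit(
        K_D=float(kd),
        B_max=float(bmax),
        K_D_ci95=(float(kd - tval * se[1]), float(kd + tval * se[1])),
        B_max_ci95=(float(bmax - tval * se[0]), float(bmax + tval * se[0])),
        residuals=resid,
    )
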