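"""Continuous-time Markov chains over discrete current levels.

Within one trapping event the protein hops between residence sites; the
emitted current is a telegraph-like process over the corresponding
blockade levels.  This module provides the rate-matrix algebra behind the
long-trace generator:

* building a reversible "star" rate matrix whose stationary distribution
  equals prescribed level occupancies (transitions run through the
  dominant level, which is how the minor levels appear as excursions from
  the main blockade level);
* the analytic autocovariance and one-sided power spectral density of the
  level process, via spectral decomposition of the symmetrized generator
  (a sum of Lorentzians, one per relaxation mode);
* band-limited and filter-weighted variances, used to calibrate switch
  rates so that a profile's measured low-frequency current noise matches a
  target RMS;
* exact jump-chain sampling of state paths.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "validate_rate_matrix",
    "stationary_distribution",
    "star_rate_matrix",
    "psd_modes",
    "psd_one_sided",
    "band_variance",
    "weighted_variance",
    "sample_path",
]


def validate_rate_matrix(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("rate matrix must be square")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal rates must be non-negative")
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-9 * max(1.0, np.abs(Q).max())):
        raise ValueError("rate-matrix rows must sum to zero")
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution π with πQ = 0, Σπ = 1."""
    Q = validate_rate_matrix(Q)
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def star_rate_matrix(occupancies: np.ndarray, exit_rates: np.ndarray | float) -> np.ndarray:
    """Reversible star-topology rate matrix with given stationary law.

    Parameters
    ----------
    occupancies:
        Target stationary probabilities π (must sum to 1).  The hub is the
        state with the largest occupancy; all transitions go through it.
    exit_rates:
        Mean exit rate (1/sojourn, s⁻¹) of each non-hub state; a scalar is
        broadcast.  Hub exit rates follow from detailed balance,
        ``k_hub->i = π_i / π_hub * k_i->hub``.

    States with zero occupancy are kept in the matrix but isolated.
    """
    pi = np.asarray(occupancies, dtype=float)
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("occupancies must be non-negative and sum to 1")
    n = pi.size
    hub = int(np.argmax(pi))
    rates = np.broadcast_to(np.asarray(exit_rates, dtype=float), (n,)).copy()
    Q = np.zeros((n, n))
    for i in range(n):
        if i == hub or pi[i] == 0.0:
            continue
        Q[i, hub] = rates[i]
        Q[hub, i] = pi[i] / pi[hub] * rates[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def psd_modes(Q: np.ndarray, levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relaxation modes of the centered level process.

    For a reversible chain the autocovariance is C(t) = Σ_k c_k e^{-λ_k t}
    with λ_k > 0 the nonzero eigenvalues of -Q and c_k ≥ 0 the squared
    projections of the (centered) level vector on the eigenmodes of the
    symmetrized generator.  Returns ``(lambdas, weights)``; Σ c_k equals
    the stationary variance of the level process.
    """
    Q = validate_rate_matrix(Q)
    levels = np.asarray(levels, dtype=float)
    pi = stationary_distribution(Q)
    live = pi > 0
    Ql = Q[np.ix_(live, live)]
    pil = pi[live] / pi[live].sum()
    vl = levels[live]
    d = np.sqrt(pil)
    S = (Ql / d[None, :]) * d[:, None]  # D^{1/2} Q D^{-1/2}, symmetric if reversible
    S = 0.5 * (S + S.T)
    w, U = np.linalg.eigh(S)
    proj = U.T @ (d * vl)
    lam = -w
    keep = lam > 1e-12 * max(1.0, lam.max(initial=0.0))
    return lam[keep], proj[keep] ** 2


def psd_one_sided(Q: np.ndarray, levels: np.ndarray, freqs_hz: np.ndarray) -> np.ndarray:
    """One-sided PSD of the level process, units²/Hz.

    ``S(f) = Σ_k 4 c_k λ_k / (λ_k² + (2πf)²)``; integrating over f ≥ 0
    recovers the stationary variance.
    """
    lam, c = psd_modes(Q, levels)
    f = np.asarray(freqs_hz, dtype=float)
    w2 = (2.0 * np.pi * f[..., None]) ** 2
    return np.sum(4.0 * c * lam / (lam**2 + w2), axis=-1)


def band_variance(Q: np.ndarray, levels: np.ndarray, f_lo: float, f_hi: float) -> float:
    """Exact integral of the one-sided PSD over [f_lo, f_hi]."""
    lam, c = psd_modes(Q, levels)
    if lam.size == 0:
        return 0.0
    term = np.arctan(2.0 * np.pi * f_hi / lam) - np.arctan(2.0 * np.pi * f_lo / lam)
    return float(np.sum(c * 2.0 / np.pi * term))


def weighted_variance(
    Q: np.ndarray,
    levels: np.ndarray,
    weight,
    f_max: float,
    n_grid: int = 4096,
) -> float:
    """∫₀^{f_max} S(f) w(f) df with an arbitrary spectral weight.

    ``weight`` maps a frequency array (Hz) to |H(f)|²-like factors.  The
    integral uses a dense log-linear grid so narrow Lorentzians near DC
    are resolved.
    """
    lam, c = psd_modes(Q, levels)
    if lam.size == 0:
        return 0.0
    f_small = max(min(lam.min() / (2 * np.pi) * 1e-3, f_max * 1e-6), 1e-9)
    grid = np.unique(
        np.concatenate(
            [
                np.array([0.0]),
                np.geomspace(f_small, f_max, n_grid // 2),
                np.linspace(0.0, f_max, n_grid // 2),
            ]
        )
    )
    S = psd_one_sided(Q, levels, grid)
    return float(np.trapezoid(S * weight(grid), grid))


def sample_path(
    Q: np.ndarray,
    duration_s: float,
    rng: np.random.Generator,
    initial_state: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a state path over [0, duration].

    Returns ``(states, switch_times)``: ``states[i]`` is occupied during
    ``[switch_times[i], switch_times[i+1])``, with ``switch_times[0] = 0``
    and an implicit final boundary at ``duration_s``.  The initial state
    is drawn from the stationary distribution unless given.
    """
    Q = validate_rate_matrix(Q)
    pi = stationary_distribution(Q)
    if initial_state is None:
        state = int(rng.choice(pi.size, p=pi))
    else:
        state = int(initial_state)
    states, times = [state], [0.0]
    t = 0.0
    while True:
        exit_rate = -Q[state, state]
        if exit_rate <= 0:
            break
        t += rng.exponential(1.0 / exit_rate)
        if t >= duration_s:
            break
        probs = Q[state].copy()
        probs[state] = 0.0
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum()
        state = int(rng.choice(pi.size, p=probs))
        states.append(state)
        times.append(t)
    return np.asarray(states, dtype=np.int64), np.asarray(times, dtype=float)
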