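"""Overdamped Brownian dynamics in a 1D free-energy landscape.

The integrator is the Ermak–McCammon update

    z(t + dt) = z(t) + (D / kT) F(z) dt + S,

with F(z) = -dΔG/dz taken from the landscape (ΔG in kT, so D/kT·F is
simply D·F with F in kT/nm) and S a centered normal increment of variance
2 D dt.  The constriction end is reflecting; the cis exit is absorbing and
terminates the trajectory (the protein escapes the pore).

Defaults follow protein-in-pore scales: D = 10 nm²/µs and dt = 1e-4 µs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import FreeEnergyLandscape

__all__ = ["BDParams", "BDResult", "simulate_bd", "simulate_bd_ensemble"]


@dataclass(frozen=True)
class BDParams:
    diffusion_D: float = 10.0  # nm²/µs
    timestep_dt: float = 1e-4  # µs
    z_min_reflecting: float = 2.0  # nm
    z_max_absorbing: float | None = 13.0  # nm; None disables absorption
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.diffusion_D <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if self.timestep_dt <= 0:
            raise ValueError("timestep must be positive")
        if self.z_max_absorbing is not None and self.z_min_reflecting >= self.z_max_absorbing:
            raise ValueError("z_min_reflecting must lie below z_max_absorbing")


@dataclass
class BDResult:
    """Trajectory in nm sampled every timestep, plus escape information."""

    positions: np.ndarray  # (n,) for a single walker, (n, m) for an ensemble
    dt_us: float
    escaped: np.ndarray  # bool per walker
    escape_step: np.ndarray  # int per walker, -1 if never absorbed

    @property
    def times_us(self) -> np.ndarray:
        return np.arange(self.positions.shape[0]) * self.dt_us


def _check_stability(landscape: FreeEnergyLandscape, params: BDParams) -> None:
    max_force = float(np.max(np.abs(landscape.force(landscape.z_grid))))
    span = landscape.z_max - landscape.z_min
    if params.diffusion_D * max_force * params.timestep_dt > span:
        raise ValueError(
            "timestep too large: drift per step exceeds the landscape span"
        )


def simulate_bd(
    landscape: FreeEnergyLandscape,
    params: BDParams,
    n_steps: int,
    z0: float | None = None,
) -> BDResult:
    """Integrate a single trajectory.

    Returns the positions including the initial condition; if the walker
    is absorbed at ``z_max_absorbing`` the trajectory is truncated at the
    absorption step.
    """
    res = simulate_bd_ensemble(landscape, params, n_steps, z0=z0, n_walkers=1)
    traj = res.positions[:, 0]
    if res.escaped[0]:
        traj = traj[: res.escape_step[0] + 1]
    return BDResult(
        positions=traj,
        dt_us=params.timestep_dt,
        escaped=res.escaped[:1],
        escape_step=res.escape_step[:1],
    )


def simulate_bd_ensemble(
    landscape: FreeEnergyLandscape,
    params: BDParams,
    n_steps: int,
    n_walkers: int = 1,
    z0: float | np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> BDResult:
    """Integrate many independent walkers simultaneously.

    Absorbed walkers stop moving; their last position is held so the
    output array stays rectangular (use ``escape_step`` to trim).
    """
    _check_stability(landscape, params)
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    lo = params.z_min_reflecting
    hi = params.z_max_absorbing
    if z0 is None:
        z0 = 0.5 * (landscape.z_min + landscape.z_max)
    z = np.broadcast_to(np.asarray(z0, dtype=float), (n_walkers,)).copy()
    if np.any(z < lo) or (hi is not None and np.any(z > hi)):
        raise ValueError("initial position outside [z_min, z_max]")

    D, dt = params.diffusion_D, params.timestep_dt
    sigma = np.sqrt(2.0 * D * dt)
    grid, force_grid = landscape.z_grid, landscape._force

    out = np.empty((n_steps + 1, n_walkers))
    out[0] = z
    alive = np.ones(n_walkers, dtype=bool)
    escape_step = np.full(n_walkers, -1, dtype=np.int64)

    for i in range(1, n_steps + 1):
        if alive.any():
            f = np.interp(z[alive], grid, force_grid)
            step = D * f * dt + sigma * rng.standard_normal(alive.sum())
            znew = z[alive] + step
            # reflecting lower boundary
            below = znew < lo
            znew[below] = 2.0 * lo - znew[below]
            np.clip(znew, lo, None, out=znew)
            z[alive] = znew
            if hi is not None:
                hit = z >= hi
                newly = hit & alive
                if newly.any():
                    z[newly] = hi
                    escape_step[newly] = i
                    alive &= ~hit
        out[i] = z
    return BDResult(
        positions=out,
        dt_us=dt,
        escaped=escape_step >= 0,
        escape_step=escape_step,
    )
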