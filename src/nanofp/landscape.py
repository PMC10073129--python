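"""Free-energy landscapes along the pore axis.

The trapped protein's axial motion is modeled as 1D diffusion in a
potential of mean force ΔG(z) over z in [2, 13] nm: a double well whose
minima are the two residence sites (deep site near z = 4 nm, shallow site
near z = 10 nm), separated by a barrier, with a steep wall at the
constriction end and a modest escape barrier toward the cis exit where the
trajectory is absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .constants import kcal_per_mol_to_kt

__all__ = ["FreeEnergyLandscape", "build_landscape", "harmonic_landscape", "flat_landscape"]

Z_MIN_DEFAULT = 2.0
Z_MAX_DEFAULT = 13.0


@dataclass
class FreeEnergyLandscape:
    """ΔG(z) on a strictly increasing grid, in kT.

    The force field F(z) = -dΔG/dz (kT/nm) is computed once by central
    finite differences and evaluated by linear interpolation.
    """

    z_grid: np.ndarray  # nm, strictly increasing
    deltaG: np.ndarray  # kT
    voltage_label: float = 100.0  # mV, provenance only
    _force: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.deltaG = np.asarray(self.deltaG, dtype=float)
        if self.z_grid.ndim != 1 or self.z_grid.size < 2:
            raise ValueError("z_grid must be a 1D array with at least 2 points")
        if not np.all(np.diff(self.z_grid) > 0):
            raise ValueError("z_grid must be strictly increasing")
        if self.deltaG.shape != self.z_grid.shape:
            raise ValueError("deltaG must match z_grid in shape")
        if not np.all(np.isfinite(self.deltaG)):
            raise ValueError("deltaG must be finite everywhere")
        self._force = -np.gradient(self.deltaG, self.z_grid)

    @property
    def z_min(self) -> float:
        return float(self.z_grid[0])

    @property
    def z_max(self) -> float:
        return float(self.z_grid[-1])

    def energy(self, z):
        return np.interp(z, self.z_grid, self.deltaG)

    def force(self, z):
        """Force -dΔG/dz in kT/nm, clamped to the grid ends."""
        return np.interp(z, self.z_grid, self._force)


def build_landscape(
    anchors: list[tuple[float, float]],
    voltage: float = 100.0,
    barrier_height: float = 3.0,
    anchor_units: str = "kcal/mol",
    z_min: float = Z_MIN_DEFAULT,
    z_max: float = Z_MAX_DEFAULT,
    wall_height: float = 8.0,
    escape_barrier: float = 1.0,
    n_grid: int = 441,
) -> FreeEnergyLandscape:
    """Construct a smooth double-well ΔG(z) through anchor points.

    Parameters
    ----------
    anchors:
        ``[(z1, G1), (z2, G2)]`` well minima inside (z_min, z_max); the
        energy differences between anchors are preserved exactly.
    barrier_height:
        Height in kT of the single barrier between the two wells,
        measured from the shallower well.
    anchor_units:
        ``"kcal/mol"`` (converted at 298.15 K) or ``"kT"``.
    wall_height, escape_barrier:
        kT rise of ΔG at the reflecting (constriction) end and at the
        absorbing (escape) end, relative to the adjacent well.

    The curve is a monotone-segment PCHIP through the control points, so it
    has exactly one interior maximum between the wells, passes through the
    anchors, and has zero slope (zero force) at each well minimum.
    """
    if len(anchors) < 2:
        raise ValueError("need at least two anchors")
    anchors = sorted(anchors)
    for z, _ in anchors:
        if not (z_min < z < z_max):
            raise ValueError(f"anchor position {z} nm outside ({z_min}, {z_max}) nm")
    if anchor_units == "kcal/mol":
        anchors = [(z, kcal_per_mol_to_kt(g)) for z, g in anchors]
    elif anchor_units != "kT":
        raise ValueError("anchor_units must be 'kcal/mol' or 'kT'")

    (z1, g1), (z2, g2) = anchors[0], anchors[-1]
    z_bar = 0.5 * (z1 + z2)
    g_bar = max(g1, g2) + barrier_height
    pts_z = [z_min, z1, z_bar, z2, z_max]
    pts_g = [g1 + wall_height, g1, g_bar, g2, g2 + escape_barrier]
    # guard against coincident control points when anchors hug the edges
    if len(set(pts_z)) != len(pts_z):
        raise ValueError("anchors too close to the domain edges")
    interp = PchipInterpolator(pts_z, pts_g)
    z_grid = np.linspace(z_min, z_max, n_grid)
    return FreeEnergyLandscape(z_grid=z_grid, deltaG=interp(z_grid), voltage_label=voltage)


def harmonic_landscape(
    kappa_kt_per_nm2: float,
    center: float = 7.5,
    z_min: float = Z_MIN_DEFAULT,
    z_max: float = Z_MAX_DEFAULT,
    n_grid: int = 441,
) -> FreeEnergyLandscape:
    """Harmonic well ΔG = ½κ(z-c)², handy for integrator validation."""
    z = np.linspace(z_min, z_max, n_grid)
    return FreeEnergyLandscape(z_grid=z, deltaG=0.5 * kappa_kt_per_nm2 * (z - center) ** 2)


def flat_landscape(
    z_min: float = Z_MIN_DEFAULT, z_max: float = Z_MAX_DEFAULT, n_grid: int = 51
) -> FreeEnergyLandscape:
    """Zero-force landscape (free diffusion)."""
    z = np.linspace(z_min, z_max, n_grid)
    return FreeEnergyLandscape(z_grid=z, deltaG=np.zeros_like(z))
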