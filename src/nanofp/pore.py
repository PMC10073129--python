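"""Closed-form pore biophysics for funnel-shaped channels.

Three small calculations characterize an open pore electrically:

* the access-corrected resistance of a funnel (tapered cylinder) of length
  ``L`` between entry and exit diameters ``d_in``/``d_out``,
  ``R = 4 L / (sigma_s * pi * d_in * d_out)``, which degenerates to the
  familiar uniform-cylinder formula when the two diameters are equal;
* the Goldman–Hodgkin–Katz permeability ratio ``P_K+/P_Cl-`` of a
  cation-selective pore from the reversal potential measured under an
  asymmetric KCl gradient, with single-salt activities taken as mean
  activity coefficient × molarity;
* conversion of an ion crossing rate (events/ns, e.g. from MD flux
  counting) to an electrical current in pA.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
import math

from .constants import ELEMENTARY_CHARGE, T_DEFAULT, thermal_voltage_mv

__all__ = [
    "PoreSpec",
    "IonConditions",
    "SelectivityResult",
    "Diameter",
    "funnel_conductance",
    "ghk_selectivity",
    "flux_to_current",
    "YAXAB_C8",
]


class Diameter(str, Enum):
    """Which diameter of the pore geometry plays d_in / d_out."""

    CIS_ENTRY = "cis_entry"
    CONSTRICTION = "constriction"
    TRANS_EXIT = "trans_exit"


@dataclass(frozen=True)
class PoreSpec:
    """Funnel pore geometry (all lengths in nm)."""

    symmetry_label: str
    channel_length_L: float
    d_cis_entry: float
    d_trans_exit: float
    d_constriction: float

    def __post_init__(self) -> None:
        for name in ("channel_length_L", "d_cis_entry", "d_trans_exit", "d_constriction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_constriction > self.d_cis_entry:
            raise ValueError("constriction cannot be wider than the cis entry")

    def diameter(self, which: Diameter | str) -> float:
        which = Diameter(which)
        return {
            Diameter.CIS_ENTRY: self.d_cis_entry,
            Diameter.CONSTRICTION: self.d_constriction,
            Diameter.TRANS_EXIT: self.d_trans_exit,
        }[which]


#: The C8 oligomer geometry: ~18 nm long funnel, 10 nm cis entry,
#: 2.7 nm trans exit, 1.9 nm constriction.
YAXAB_C8 = PoreSpec(
    symmetry_label="C8",
    channel_length_L=18.0,
    d_cis_entry=10.0,
    d_trans_exit=2.7,
    d_constriction=1.9,
)


@dataclass(frozen=True)
class IonConditions:
    """Salt and solution conditions on both sides of the membrane."""

    cis_molarity: float
    trans_molarity: float
    cis_activity_coeff: float
    trans_activity_coeff: float
    temperature: float = T_DEFAULT
    solution_conductivity_sigma_s: float | None = None  # S/m

    def __post_init__(self) -> None:
        if self.cis_molarity <= 0 or self.trans_molarity <= 0:
            raise ValueError("molarities must be positive")
        for name in ("cis_activity_coeff", "trans_activity_coeff"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def cis_activity(self) -> float:
        """Single-salt activity on the cis side, mol/L."""
        return self.cis_activity_coeff * self.cis_molarity

    @property
    def trans_activity(self) -> float:
        return self.trans_activity_coeff * self.trans_molarity


@dataclass(frozen=True)
class SelectivityResult:
    reversal_potential_Vr: float  # mV
    permeability_ratio_PK_over_PCl: float

    def __post_init__(self) -> None:
        if self.permeability_ratio_PK_over_PCl <= 0:
            raise ValueError("permeability ratio must be positive")


def funnel_conductance(
    pore: PoreSpec,
    sigma_s: float,
    d_in: Diameter | str = Diameter.CIS_ENTRY,
    d_out: Diameter | str = Diameter.CONSTRICTION,
) -> float:
    """Open-pore conductance of a funnel, in nS.

    ``G = 1/R`` with ``R = 4 L / (sigma_s * pi * d_in * d_out)``.  With
    ``sigma_s`` in S/m and lengths in nm the result is directly in nS.

    Parameters
    ----------
    pore:
        Funnel geometry.
    sigma_s:
        Electrolyte solution conductivity, S/m.
    d_in, d_out:
        Which geometric diameters play the entry/exit role; the default
        pairs the cis entry with the constriction.
    """
    if sigma_s <= 0:
        raise ValueError("solution conductivity must be positive")
    din = pore.diameter(d_in)
    dout = pore.diameter(d_out)
    return sigma_s * math.pi * din * dout / (4.0 * pore.channel_length_L)


def ghk_selectivity(conditions: IonConditions, Vr_mv: float) -> SelectivityResult:
    """Cation/anion permeability ratio from a reversal potential.

    Implements the Goldman–Hodgkin–Katz relation for a single binary salt
    (KCl)::

        P_K/P_Cl = (a_cis - a_trans * e^{Vr F / RT})
                   / (a_cis * e^{Vr F / RT} - a_trans)

    where ``a`` are the K+/Cl- activities (equal for the single salt on
    each side) and Vr is measured with the working electrode on the cis
    side.  Vr = 0 gives a ratio of exactly 1 (non-selective pore).

    Raises
    ------
    ZeroDivisionError
        If Vr sits at the K+ Nernst potential, where the denominator
        vanishes.
    """
    a_cis = conditions.cis_activity
    a_trans = conditions.trans_activity
    x = math.exp(Vr_mv / thermal_voltage_mv(conditions.temperature))
    denom = a_cis * x - a_trans
    if abs(denom) < 1e-12 * max(a_cis, a_trans):
        raise ZeroDivisionError(
            "reversal potential equals the K+ Nernst potential; "
            "permeability ratio diverges"
        )
    ratio = (a_cis - a_trans * x) / denom
    if ratio <= 0:
        # Vr outside the interval between the two Nernst potentials: the
        # expression changes sign across the singularity
        raise ZeroDivisionError(
            "reversal potential at or beyond the K+ Nernst potential; "
            "no physical permeability ratio"
        )
    return SelectivityResult(reversal_potential_Vr=Vr_mv, permeability_ratio_PK_over_PCl=ratio)


def flux_to_current(crossing_rate_per_ns: float, valence: int) -> float:
    """Convert an ion crossing rate to current.

    ``I = rate * |z| * e``; 1 ns⁻¹ of a monovalent ion corresponds to
    160.218 pA.
    """
    if crossing_rate_per_ns < 0:
        raise ValueError("crossing rate must be non-negative")
    return crossing_rate_per_ns * 1e9 * abs(valence) * ELEMENTARY_CHARGE * 1e12
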