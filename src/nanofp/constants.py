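"""Physical constants and unit conversions used across the package.

All trace currents are in pA, lengths along the pore axis in nm, times in
seconds unless a function states otherwise (the Brownian integrator works
in µs internally, matching its natural diffusion units of nm²/µs).
"""

from scipy import constants as _sc

#: Elementary charge, C.
ELEMENTARY_CHARGE = _sc.elementary_charge

#: Gas constant, J/(mol K).
GAS_CONSTANT = _sc.R

#: Faraday constant, C/mol.
FARADAY = _sc.value("Faraday constant")

#: Default temperature (25 °C), K.
T_DEFAULT = 298.15


def thermal_voltage_mv(temperature_k: float = T_DEFAULT) -> float:
    """RT/F in mV (25.693 mV at 298.15 K)."""
    return GAS_CONSTANT * temperature_k / FARADAY * 1e3


def kcal_per_mol_to_kt(energy_kcal_mol: float, temperature_k: float = T_DEFAULT) -> float:
    """Convert kcal/mol to units of kT (1 kcal/mol = 1.688 kT at 298.15 K)."""
    kt_kcal = GAS_CONSTANT * temperature_k / _sc.calorie / 1e3  # kcal/mol per kT
    return energy_kcal_mol / kt_kcal


def kt_to_kcal_per_mol(energy_kt: float, temperature_k: float = T_DEFAULT) -> float:
    """Convert kT units back to kcal/mol."""
    kt_kcal = GAS_CONSTANT * temperature_k / _sc.calorie / 1e3
    return energy_kt * kt_kcal
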