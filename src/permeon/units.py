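"""Physical constants and unit conversions.

The package works internally in thermal units (kBT) at the simulation
temperature, ångström for length and nanoseconds for time. Conversions to
SI happen only at the conductance boundary (Eq.-of-state: charge in
coulomb, voltage in volts, conductance in picosiemens).
"""

from __future__ import annotations

BOLTZMANN_J_PER_K = 1.380649e-23
ELEMENTARY_CHARGE_C = 1.602176634e-19
AVOGADRO = 6.02214076e23
GAS_CONSTANT_KJ_PER_MOL_K = BOLTZMANN_J_PER_K * AVOGADRO / 1000.0

#: Default simulation temperature (K) used for all kBT conversions.
DEFAULT_TEMPERATURE_K = 310.0


def kBT_joule(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy kB*T in joule."""
    return BOLTZMANN_J_PER_K * temperature_K


def kBT_kJ_per_mol(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy in kJ/mol (R*T)."""
    return GAS_CONSTANT_KJ_PER_MOL_K * temperature_K


def kj_per_mol_to_kBT(value: float, temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Convert an energy from kJ/mol to kBT."""
    return value / kBT_kJ_per_mol(temperature_K)


def spring_kj_mol_nm2_to_kBT_A2(
    k: float, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Convert a harmonic spring constant from kJ mol^-1 nm^-2 to kBT Å^-2.

    1 nm^2 = 100 Å^2, so k [kJ/mol/Å^2] = k [kJ/mol/nm^2] / 100.
    """
    return k / 100.0 / kBT_kJ_per_mol(temperature_K)


def voltage_mV_to_kBT_per_e(
    voltage_mV: float, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Energy (kBT) gained by a +1e charge crossing the full voltage drop.

    At 310 K, 1 kBT/e corresponds to ~26.7 mV.
    """
    return voltage_mV * 1e-3 * ELEMENTARY_CHARGE_C / kBT_joule(temperature_K)
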