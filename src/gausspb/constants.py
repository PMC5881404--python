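"""Physical constants and unit conversions.

Internal unit system follows the DelPhi/APBS convention: lengths in
angstroms, charges in units of the elementary charge, energies in
kcal/mol and electrostatic potentials in kT/e.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA 2018 values, SI units. Immutable."""

    avogadro: float = 6.02214076e23        # 1/mol
    elementary_charge: float = 1.602176634e-19   # C
    vacuum_permittivity: float = 8.8541878128e-12  # F/m
    gas_constant: float = 8.31446261815324         # J/(mol K)
    boltzmann: float = 1.380649e-23                # J/K


CODATA = PhysicalConstants()

#: Coulomb constant in kcal·Å/(mol·e²): q1*q2*KCOUL/(eps*r) is an energy
#: in kcal/mol when q is in e and r in Å.
KCOUL = 332.0637

#: Gas constant in kcal/(mol·K).
R_KCAL = CODATA.gas_constant / 4184.0

#: Joules per kcal.
JOULES_PER_KCAL = 4184.0

#: mol/L -> particles/Å³  (N_A / 1e27).
MOLAR_TO_PER_A3 = CODATA.avogadro / 1.0e27


def kT_kcal(temperature: float) -> float:
    """Thermal energy RT in kcal/mol at the given temperature (K)."""
    return R_KCAL * temperature
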