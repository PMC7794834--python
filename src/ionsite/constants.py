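"""Physical constants in the package's working units (kcal/mol, Angstrom, e).

CODATA 2018 values.  The two derived constants below are the only ones the
electrostatics ever needs:

* ``COULOMB_KCAL`` = N_A e^2 / (4 pi eps0), in kcal*A/mol.  The vacuum
  interaction energy of two unit charges 1 A apart.
* ``BOLTZMANN_KCAL`` = k_B N_A, in kcal/(mol K).  The molar gas constant.
"""

from __future__ import annotations

from dataclasses import dataclass

# CODATA 2018 exact values
_E_CHARGE = 1.602176634e-19  # C
_EPS0 = 8.8541878128e-12  # F/m
_N_AVOGADRO = 6.02214076e23  # 1/mol
_K_BOLTZMANN = 1.380649e-23  # J/K
_J_PER_KCAL = 4184.0

#: N_A e^2 / (4 pi eps0) in kcal*A/mol  (~332.0637)
COULOMB_KCAL = (
    _E_CHARGE**2 / (4.0 * 3.141592653589793 * _EPS0) * _N_AVOGADRO * 1e10 / _J_PER_KCAL
)

#: k_B N_A in kcal/(mol K)  (~0.0019872)
BOLTZMANN_KCAL = _K_BOLTZMANN * _N_AVOGADRO / _J_PER_KCAL

#: default temperature, K
DEFAULT_TEMPERATURE = 298.15


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable constant bundle threaded through energy evaluations."""

    coulomb_kcal: float = COULOMB_KCAL
    boltzmann_kcal: float = BOLTZMANN_KCAL


CONSTANTS = PhysicalConstants()


def kt_kcal(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B T in kcal/mol (0.5925 at 298.15 K)."""
    return BOLTZMANN_KCAL * temperature
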