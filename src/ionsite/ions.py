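"""Ion species and the Born-style desolvation penalty.

An ion of valence z and effective radius r0 moving from bulk water
(permittivity eps_w) into a region of local permittivity eps_r pays

    dG_solv = (N_A z^2 e^2) / (8 pi eps0 r0) * (1/eps_r - 1/eps_w)

which is >= 0 whenever eps_r <= eps_w: the smooth dielectric makes this a
smooth penalty ramp instead of a hard solute boundary.  For efficiency the
effective radius is 2.0 A for both cations and anions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .constants import CONSTANTS, PhysicalConstants
from .dielectric import DielectricField

__all__ = [
    "IonSpec",
    "ION_TABLE",
    "get_ion",
    "desolvation_penalty",
    "averaged_local_dielectric",
]


@dataclass(frozen=True)
class IonSpec:
    """One mobile ion species.

    ``effective_radius`` (r0) enters the Born penalty; ``clash_radius``
    (R_ion) enters the steric filter.  They default to the same 2.0 A.
    """

    species: str
    valence: int
    effective_radius: float = 2.0
    clash_radius: float = 2.0

    def __post_init__(self) -> None:
        if self.valence == 0:
            raise ValueError("ion valence must be nonzero")
        if not (self.effective_radius > 0 and self.clash_radius > 0):
            raise ValueError("ion radii must be positive")

    @property
    def charge(self) -> float:
        """q_ion in elementary charges (equals the valence)."""
        return float(self.valence)


#: The four benchmarked species.
ION_TABLE: dict[str, IonSpec] = {
    "CA2": IonSpec("CA2", +2),
    "MG2": IonSpec("MG2", +2),
    "ZN2": IonSpec("ZN2", +2),
    "CL1": IonSpec("CL1", -1),
}


def get_ion(species: str) -> IonSpec:
    """Look up a built-in ion by name (case-insensitive)."""
    key = species.upper()
    if key not in ION_TABLE:
        raise KeyError(
            f"unknown ion species {species!r}; built-in: {sorted(ION_TABLE)}")
    return ION_TABLE[key]


def desolvation_penalty(ion: IonSpec, eps_local, eps_w: float,
                        constants: PhysicalConstants = CONSTANTS
                        ) -> Union[float, np.ndarray]:
    """Born penalty (kcal/mol) for the ion at local permittivity ``eps_local``.

    Accepts a scalar or array ``eps_local``; values must be >= 1.
    """
    eps_local = np.asarray(eps_local, dtype=float)
    if np.any(eps_local < 1.0):
        raise ValueError("eps_local must be >= 1")
    out = (constants.coulomb_kcal / (2.0 * ion.effective_radius)
           * ion.valence**2 * (1.0 / eps_local - 1.0 / eps_w))
    return float(out) if out.ndim == 0 else out


def averaged_local_dielectric(eps: DielectricField, node: tuple[int, int, int]) -> float:
    """Mean of the six edge-midpoint eps values around an interior node."""
    i, j, k = node
    n = eps.grid.n
    if not (0 < i < n - 1 and 0 < j < n - 1 and 0 < k < n - 1):
        raise IndexError(f"node {node} is not interior to a {n}^3 grid")
    ex, ey, ez = eps.eps_mid
    return float((ex[i - 1, j, k] + ex[i, j, k]
                  + ey[i, j - 1, k] + ey[i, j, k]
                  + ez[i, j, k - 1] + ez[i, j, k]) / 6.0)
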