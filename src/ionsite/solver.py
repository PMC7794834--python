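"""Finite-difference solver for the desolvation-modified Poisson-Boltzmann
equation on the cubic lattice.

The equation solved (potential phi in units of kT/e) is

    div( eps(r) grad phi ) = -4 pi C [ rho_solute
        + sum_i z_i c_bulk lam_i(r) exp(-z_i phi(r)) ]

where C = N_A e^2/(4 pi eps0 k_B T) converts e/A charge densities to kT/e
potentials, and lam_i = exp(-dG_solv,i / RT) is the ion accessibility: the
Born desolvation penalty of mobile species i at the node's local (smoothly
varying) permittivity, placed inside the Boltzmann factor so that mobile
ions are excluded from the solute body without any sharp boundary.

Discretization is the standard flux-conservative 7-point stencil with the
permittivity evaluated on edge midpoints.  Relaxation is Gauss-Seidel with
red-black ordering and optional over-relaxation; boundary values are fixed
to the Debye-Hueckel superposition of atom charges.  In ``linear`` mode the
mobile-ion term is replaced by its first-order linearization
-kbar^2(r) phi with kbar^2 proportional to lam * sum z_i^2 c_bulk; in
``nonlinear`` mode the full Boltzmann source is iterated with the linear
part treated implicitly (Picard splitting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import numpy as np

from .constants import BOLTZMANN_KCAL, COULOMB_KCAL, DEFAULT_TEMPERATURE
from .dielectric import DielectricField
from .grid import GridSpec, grid_to_world
from .ions import IonSpec, desolvation_penalty
from .structure import Structure

__all__ = [
    "SolverConfig",
    "PotentialMap",
    "GeometryError",
    "NumericalError",
    "spread_charges",
    "boundary_potential",
    "ion_accessibility",
    "debye_kappa",
    "solve",
]

#: ions per A^3 at 1 mol/L
_NUMBER_DENSITY_PER_MOLAR = 6.02214076e-4


class GeometryError(ValueError):
    pass


class NumericalError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverConfig:
    """Mobile-ion and relaxation parameters.

    ``ion_valences`` lists the mobile species (all at ``salt_conc``); they
    must be electroneutral as a set.  ``ion_radius`` is the effective Born
    radius used for the mobile-ion accessibility weight.
    """

    salt_conc: float = 0.5  # mol/L
    temperature: float = DEFAULT_TEMPERATURE  # K
    ion_valences: tuple[int, ...] = (1, -1)
    ion_radius: float = 2.0  # A
    tolerance: float = 1e-4  # kT/e, max update per sweep
    max_iterations: int = 2000
    mode: str = "linear"  # or "nonlinear"
    omega: Optional[float] = None  # over-relaxation; None = auto

    def __post_init__(self) -> None:
        if self.salt_conc < 0:
            raise ValueError("salt_conc must be >= 0")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")
        if sum(self.ion_valences) != 0:
            raise ValueError(
                f"mobile species {self.ion_valences} are not electroneutral "
                "at equal concentrations")
        if self.mode not in ("linear", "nonlinear"):
            raise ValueError(f"mode must be linear or nonlinear, got {self.mode!r}")
        if self.omega is not None and not (1.0 <= self.omega < 2.0):
            raise ValueError("omega must be in [1, 2)")

    @property
    def rt_kcal(self) -> float:
        return BOLTZMANN_KCAL * self.temperature

    @property
    def coulomb_kt(self) -> float:
        """C = Coulomb constant in A*kT/e^2 at this temperature."""
        return COULOMB_KCAL / self.rt_kcal


@dataclass
class PotentialMap:
    """Electrostatic potential on grid nodes, kT/e."""

    grid: GridSpec
    phi: np.ndarray  # (n, n, n)
    iterations_used: int
    converged: bool
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def at_node(self, node: tuple[int, int, int]) -> float:
        return float(self.phi[node])


def spread_charges(s: Structure, g: GridSpec) -> np.ndarray:
    """Distribute atom charges to nodes by trilinear weights (e per node)."""
    n = g.n
    q_nodes = np.zeros((n, n, n))
    frac = (s.positions - g.origin) * g.scale
    if np.any(frac <= 0) or np.any(frac >= n - 1):
        raise GeometryError("atom outside (or on the boundary of) the grid")
    i0 = np.floor(frac).astype(int)
    t = frac - i0
    for a in range(len(s)):
        q = s.atoms[a].charge
        ix, iy, iz = i0[a]
        tx, ty, tz = t[a]
        for dx, wx in ((0, 1 - tx), (1, tx)):
            for dy, wy in ((0, 1 - ty), (1, ty)):
                for dz, wz in ((0, 1 - tz), (1, tz)):
                    q_nodes[ix + dx, iy + dy, iz + dz] += q * wx * wy * wz
    return q_nodes


def debye_kappa(cfg: SolverConfig, eps_w: float) -> float:
    """Debye screening parameter kappa (1/A) in bulk solvent.

    kappa^2 = 4 pi C sum_i z_i^2 n_i / eps_w with n_i the bulk number
    density; zero at zero salt.
    """
    if cfg.salt_conc == 0:
        return 0.0
    n_num = cfg.salt_conc * _NUMBER_DENSITY_PER_MOLAR
    zsq = sum(z * z for z in cfg.ion_valences)
    return float(np.sqrt(4.0 * np.pi * cfg.coulomb_kt * zsq * n_num / eps_w))


def boundary_potential(s: Structure, g: GridSpec, cfg: SolverConfig,
                       eps_w: float = 80.0) -> np.ndarray:
    """Debye-Hueckel boundary condition: screened-Coulomb superposition.

    Returns an (n,n,n) array whose boundary nodes hold
    sum_a C q_a exp(-kappa d_a) / (eps_w d_a) in kT/e; interior is zero.
    """
    n = g.n
    out = np.zeros((n, n, n))
    mask = np.zeros((n, n, n), dtype=bool)
    mask[[0, -1], :, :] = True
    mask[:, [0, -1], :] = True
    mask[:, :, [0, -1]] = True
    idx = np.argwhere(mask)
    coords = g.origin + idx * g.h
    kappa = debye_kappa(cfg, eps_w)
    vals = np.zeros(len(idx))
    c_kt = cfg.coulomb_kt
    for a in s.atoms:
        if a.charge == 0.0:
            continue
        d = np.linalg.norm(coords - a.position, axis=1)
        d = np.maximum(d, g.h / 2.0)
        vals += c_kt * a.charge * np.exp(-kappa * d) / (eps_w * d)
    out[mask] = vals
    return out


def ion_accessibility(dsolv, cfg: SolverConfig) -> np.ndarray:
    """Boltzmann accessibility exp(-dG_solv/RT): 1 in bulk, ~0 in the solute."""
    dsolv = np.asarray(dsolv, dtype=float)
    if np.any(dsolv < -1e-9):
        raise ValueError("desolvation penalty must be >= 0")
    return np.exp(-np.clip(dsolv, 0.0, None) / cfg.rt_kcal)


def _species_accessibility(eps: DielectricField, cfg: SolverConfig
                           ) -> list[np.ndarray]:
    """Per-species lambda on interior nodes from the local averaged eps."""
    eps_node = eps.node_average()[1:-1, 1:-1, 1:-1]
    lams = []
    for z in cfg.ion_valences:
        probe = IonSpec(f"mobile{z:+d}", z, effective_radius=cfg.ion_radius)
        dg = desolvation_penalty(probe, eps_node, eps.params.eps_w)
        lams.append(ion_accessibility(np.clip(dg, 0.0, None), cfg))
    return lams


def solve(s: Structure, g: GridSpec, eps: DielectricField, cfg: SolverConfig,
          lam: Optional[Sequence[np.ndarray]] = None) -> PotentialMap:
    """Relax the (linearized or full) modified PBE to ``cfg.tolerance``.

    ``lam`` overrides the per-species mobile-ion accessibility with
    explicit interior-node arrays (e.g. ``lam=[ones, ones]`` recovers the
    classic sharp-free PBE with unrestricted mobile ions).
    Non-convergence is a warning, never silent; NaNs raise NumericalError.
    """
    n, h = g.n, g.h
    eps_w = eps.params.eps_w
    phi = boundary_potential(s, g, cfg, eps_w=eps_w)
    q_nodes = spread_charges(s, g)

    ex, ey, ez = eps.eps_mid
    # face permittivities for the interior block
    exm = ex[:-1, 1:-1, 1:-1]
    exp_ = ex[1:, 1:-1, 1:-1]
    eym = ey[1:-1, :-1, 1:-1]
    eyp = ey[1:-1, 1:, 1:-1]
    ezm = ez[1:-1, 1:-1, :-1]
    ezp = ez[1:-1, 1:-1, 1:]
    sum_eps = exm + exp_ + eym + eyp + ezm + ezp

    c_kt = cfg.coulomb_kt
    b_fixed = 4.0 * np.pi * c_kt * q_nodes[1:-1, 1:-1, 1:-1] / h

    n_num = cfg.salt_conc * _NUMBER_DENSITY_PER_MOLAR
    have_salt = cfg.salt_conc > 0 and len(cfg.ion_valences) > 0
    if have_salt:
        if lam is None:
            lams = _species_accessibility(eps, cfg)
        else:
            lams = [np.asarray(l, dtype=float) for l in lam]
            lams = [l[1:-1, 1:-1, 1:-1] if l.shape == (n, n, n) else l
                    for l in lams]
        z_arr = cfg.ion_valences
        # implicit (linearized) coefficient: 4 pi C h^2 sum z^2 n lam
        lin_coef = sum((z * z) * n_num * l for z, l in zip(z_arr, lams))
        denom = sum_eps + 4.0 * np.pi * c_kt * h * h * lin_coef
        # constant part of the source: 4 pi C h^2 sum z n lam (zero for
        # symmetric salts, nonzero when species accessibilities differ)
        b_const = 4.0 * np.pi * c_kt * h * h * sum(
            z * n_num * l for z, l in zip(z_arr, lams))
    else:
        denom = sum_eps
        b_const = 0.0

    interior = np.s_[1:-1, 1:-1, 1:-1]
    m = n - 2
    ii, jj, kk = np.indices((m, m, m), sparse=True)
    parity = (ii + jj + kk) % 2
    masks = [parity == 0, parity == 1]

    if cfg.omega is not None:
        omega = cfg.omega
    else:
        omega = 2.0 / (1.0 + np.sin(np.pi / n))

    residuals = []
    converged = False
    it = 0
    nonlinear = cfg.mode == "nonlinear" and have_salt
    for it in range(1, cfg.max_iterations + 1):
        max_delta = 0.0
        for mask in masks:
            phi_int = phi[interior]
            nb = (exm * phi[:-2, 1:-1, 1:-1] + exp_ * phi[2:, 1:-1, 1:-1]
                  + eym * phi[1:-1, :-2, 1:-1] + eyp * phi[1:-1, 2:, 1:-1]
                  + ezm * phi[1:-1, 1:-1, :-2] + ezp * phi[1:-1, 1:-1, 2:])
            rhs = nb + b_fixed + b_const
            if nonlinear:
                # explicit remainder of the Boltzmann source beyond its
                # linearization: sum z n lam [exp(-z phi) - 1 + z phi]
                rem = np.zeros_like(phi_int)
                for z, l in zip(z_arr, lams):
                    zphi = np.clip(z * phi_int, -50.0, 50.0)
                    rem += z * n_num * l * (np.exp(-zphi) - 1.0 + zphi)
                rhs = rhs + 4.0 * np.pi * c_kt * h * h * rem
            gs = rhs / denom
            new = phi_int + omega * (gs - phi_int)
            delta = np.abs(new[mask] - phi_int[mask]).max() if mask.any() else 0.0
            max_delta = max(max_delta, float(delta))
            phi_int[mask] = new[mask]
        if not np.isfinite(max_delta):
            raise NumericalError(f"solver diverged (NaN/Inf) at sweep {it}")
        residuals.append(max_delta)
        if max_delta <= cfg.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"PBE solver did not converge in {cfg.max_iterations} sweeps "
            f"(last max update {residuals[-1]:.3e} kT/e)", RuntimeWarning,
            stacklevel=2)
    if not np.all(np.isfinite(phi)):
        raise NumericalError("non-finite potential values after relaxation")
    return PotentialMap(grid=g, phi=phi, iterations_used=it,
                        converged=converged, residuals=np.array(residuals))


def write_map(pm: PotentialMap, dest: Union[str, Path, TextIO],
              comment: str = "") -> None:
    """Plain-text potential map: header lines then one value per node in
    C (row-major) order, kT/e."""
    if isinstance(dest, (str, Path)):
        with Path(dest).open("w") as fh:
            write_map(pm, fh, comment=comment)
        return
    g = pm.grid
    dest.write(f"# potential map (kT/e){' - ' + comment if comment else ''}\n")
    dest.write(f"# scale {g.scale} n {g.n} origin "
               f"{g.origin[0]:.6f} {g.origin[1]:.6f} {g.origin[2]:.6f}\n")
    dest.write(f"# converged {pm.converged} iterations {pm.iterations_used}\n")
    np.savetxt(dest, pm.phi.ravel(), fmt="%.6e")
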