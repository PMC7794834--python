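"""Coulomb-potential greedy ion placer (MD-setup "ionize" style reference).

The placer evaluates the plain Coulomb potential of the solute in a uniform
dielectric, then greedily drops ions one at a time at the eligible node of
minimal interaction energy q_ion * phi.  Eligible nodes lie farther than a
fixed standoff (default 6 A) from the solute's vdW surface and farther than
6 A from every already-placed ion.  After each placement the potential map
is updated with the new ion's own Coulomb contribution so later ions
respond to it.  No PBE, no desolvation: this is the contrast method that
shows what the smooth-dielectric + desolvation treatment buys.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import COULOMB_KCAL, DEFAULT_TEMPERATURE, kt_kcal
from .grid import GridSpec, build_grid
from .ions import IonSpec
from .ranking import DEFAULT_MIN_SEPARATION
from .structure import Structure

__all__ = ["PlacementError", "coulomb_map", "place_ions", "baseline_grid"]


class PlacementError(RuntimeError):
    def __init__(self, message: str, placed: list[np.ndarray]):
        super().__init__(message)
        self.placed = placed


def coulomb_map(s: Structure, g: GridSpec, eps_uniform: float = 80.0,
                temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Coulomb potential of all solute charges on every node, kT/e.

    Distances are capped below at h/2 so nodes coincident with an atom
    center stay finite.
    """
    if eps_uniform < 1.0:
        raise ValueError("eps_uniform must be >= 1")
    n = g.n
    ax = g.origin[0] + np.arange(n) * g.h
    ay = g.origin[1] + np.arange(n) * g.h
    az = g.origin[2] + np.arange(n) * g.h
    phi = np.zeros((n, n, n))
    c_kt = COULOMB_KCAL / kt_kcal(temperature)
    for a in s.atoms:
        if a.charge == 0.0:
            continue
        d2 = ((ax - a.position[0]) ** 2)[:, None, None] \
            + ((ay - a.position[1]) ** 2)[None, :, None] \
            + ((az - a.position[2]) ** 2)[None, None, :]
        d = np.maximum(np.sqrt(d2), g.h / 2.0)
        phi += c_kt * a.charge / (eps_uniform * d)
    return phi


def baseline_grid(s: Structure, min_dist_surface: float,
                  scale: float = 2.0, pad: float = 4.0) -> GridSpec:
    """Grid padded so nodes beyond the surface standoff exist on all sides."""
    lo, hi = s.bounds(include_radii=True)
    extent = float((hi - lo).max())
    side = extent + 2.0 * (min_dist_surface + pad)
    perfil = 100.0 * extent / side
    return build_grid(s, scale=scale, perfil=perfil)


def place_ions(s: Structure, n_ions: int, ion: IonSpec,
               min_dist_surface: float = 6.0, *,
               eps_uniform: float = 80.0,
               min_separation: float = DEFAULT_MIN_SEPARATION,
               scale: float = 2.0,
               grid: Optional[GridSpec] = None,
               temperature: float = DEFAULT_TEMPERATURE) -> list[np.ndarray]:
    """Greedy minimal-Coulomb-energy placement of ``n_ions`` ions.

    Returns world positions in placement order.  Raises
    :class:`PlacementError` (carrying the partial result) if eligible nodes
    run out.  Ties in energy break by lexicographic grid index, so the
    sequence is deterministic.
    """
    if n_ions < 1:
        raise ValueError("n_ions must be >= 1")
    g = grid or baseline_grid(s, min_dist_surface, scale=scale)
    n = g.n
    phi = coulomb_map(s, g, eps_uniform=eps_uniform, temperature=temperature)

    ax = g.origin[0] + np.arange(n) * g.h
    ay = g.origin[1] + np.arange(n) * g.h
    az = g.origin[2] + np.arange(n) * g.h
    # distance to the vdW surface = min over atoms of (d_center - R)
    surf = np.full((n, n, n), np.inf)
    for a in s.atoms:
        d2 = ((ax - a.position[0]) ** 2)[:, None, None] \
            + ((ay - a.position[1]) ** 2)[None, :, None] \
            + ((az - a.position[2]) ** 2)[None, None, :]
        surf = np.minimum(surf, np.sqrt(d2) - a.radius)
    eligible = surf > min_dist_surface
    eligible[[0, -1], :, :] = False
    eligible[:, [0, -1], :] = False
    eligible[:, :, [0, -1]] = False

    c_kt = COULOMB_KCAL / kt_kcal(temperature)
    placed: list[np.ndarray] = []
    for _ in range(n_ions):
        if not eligible.any():
            raise PlacementError(
                f"only {len(placed)} of {n_ions} ions could be placed "
                f"(no eligible nodes left)", placed)
        energy = np.where(eligible, ion.charge * phi, np.inf)
        flat = int(np.argmin(energy))  # argmin on C-order = lexicographic tie-break
        node = np.unravel_index(flat, energy.shape)
        pos = g.origin + np.array(node) * g.h
        placed.append(pos)
        # the new ion screens subsequent placements but not its own score
        d2 = ((ax - pos[0]) ** 2)[:, None, None] \
            + ((ay - pos[1]) ** 2)[None, :, None] \
            + ((az - pos[2]) ** 2)[None, None, :]
        d = np.maximum(np.sqrt(d2), g.h / 2.0)
        phi += c_kt * ion.charge / (eps_uniform * d)
        eligible &= d > min_separation
    return placed
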