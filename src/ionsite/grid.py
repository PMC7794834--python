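"""Cubic finite-difference lattice construction and coordinate transforms.

The lattice is vertex-centered: node (i, j, k) sits at ``origin + (i,j,k)*h``
with spacing ``h = 1/scale``.  The node count per axis is forced odd so a
central node exists.  The box side is set by the "percent fill" convention
of grid Poisson-Boltzmann solvers: the solute's largest radius-inclusive
extent occupies ``perfil`` percent of the cube side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure import Structure

__all__ = ["GridSpec", "build_grid", "world_to_grid", "grid_to_world"]


class GridParameterError(ValueError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """Cubic lattice: ``scale`` grids/A, ``n`` nodes per axis, world origin."""

    scale: float
    n: int
    origin: np.ndarray  # world position of node (0,0,0), A

    def __post_init__(self) -> None:
        if self.n < 5 or self.n % 2 == 0:
            raise GridParameterError(f"n must be odd and >= 5, got {self.n}")
        if not self.scale > 0:
            raise GridParameterError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    @property
    def h(self) -> float:
        """Grid spacing, A."""
        return 1.0 / self.scale

    @property
    def side(self) -> float:
        """Physical box side length (n-1)*h, A."""
        return (self.n - 1) * self.h

    @property
    def center(self) -> np.ndarray:
        """World position of the central node, A."""
        return self.origin + (self.n - 1) / 2.0 * self.h

    @classmethod
    def centered(cls, center, n: int, scale: float) -> "GridSpec":
        """Build a grid of ``n`` nodes per axis centered on a world point."""
        center = np.asarray(center, dtype=float)
        origin = center - (n - 1) / 2.0 * (1.0 / scale)
        return cls(scale=scale, n=n, origin=origin)

    def axes(self, offset: float = 0.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of the lattice planes along each axis.

        ``offset`` (in grid units) shifts the lattice; 0.5 gives the edge
        midpoints used for the staggered dielectric arrays.
        """
        n_pts = self.n if offset == 0.0 else self.n - 1
        idx = np.arange(n_pts) + offset
        return tuple(self.origin[ax] + idx * self.h for ax in range(3))


def build_grid(s: Structure, scale: float = 2.0, perfil: float = 70.0) -> GridSpec:
    """Cube centered on the solute with the solute filling ``perfil`` percent.

    The governing extent is the largest radius-inclusive axis extent of the
    structure; the side is that extent divided by perfil/100, and ``n`` is
    the smallest odd node count whose physical side reaches it.
    """
    if not scale > 0:
        raise GridParameterError(f"scale must be positive, got {scale}")
    if not 0 < perfil < 100:
        raise GridParameterError(
            f"perfil must be in (0, 100), got {perfil} (100 would put the "
            "solute on the boundary)")
    lo, hi = s.bounds(include_radii=True)
    extent = float((hi - lo).max())
    side = extent / (perfil / 100.0)
    h = 1.0 / scale
    n = int(math.ceil(side / h - 1e-9)) + 1
    if n % 2 == 0:
        n += 1
    n = max(n, 5)
    return GridSpec.centered((lo + hi) / 2.0, n=n, scale=scale)


def world_to_grid(g: GridSpec, p) -> np.ndarray:
    """World point (A) -> fractional grid index; inverse of grid_to_world."""
    return (np.asarray(p, dtype=float) - g.origin) * g.scale


def grid_to_world(g: GridSpec, idx) -> np.ndarray:
    """Grid index (may be fractional) -> world coordinates, A."""
    return g.origin + np.asarray(idx, dtype=float) * g.h
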