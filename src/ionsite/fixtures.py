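"""Synthetic toy structures with known analytic behavior.

These generators stand in for real protein structures in every test: a
single Born ion probes the Coulomb/Debye/Born closed forms, a dipole gives
a sign-structured field, a charged patch gives a known attraction
direction, a part-buried charged pocket contrasts the Poisson-Boltzmann +
desolvation treatment against plain Coulomb placement, and a seeded random
cluster exercises the machinery on irregular geometry.  Everything is
deterministic for a fixed seed; all fixtures fit a <= 65^3 grid at
2 grids/A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .structure import Atom, Structure

__all__ = [
    "FixtureSpec",
    "make_born_ion",
    "make_dipole",
    "make_charged_patch",
    "make_pocket",
    "make_random_cluster",
]


def _atom(serial: int, pos, charge: float, radius: float,
          name: str = "C", resname: str = "FIX", resnum: int = 1) -> Atom:
    return Atom(serial=serial, name=name, residue_name=resname, chain_id="A",
                residue_number=resnum, position=np.asarray(pos, dtype=float),
                charge=charge, radius=radius)


def make_born_ion(q: float, radius: float = 2.0, label: str = "born_ion") -> Structure:
    """Single atom at the origin: the textbook Born/Coulomb fixture."""
    if not radius > 0:
        raise ValueError("radius must be positive")
    return Structure([_atom(1, (0.0, 0.0, 0.0), q, radius, name="Q")], label=label)


def make_dipole(q: float = 0.5, separation: float = 4.0,
                radius: float = 1.8) -> Structure:
    """+q/-q pair along x, separated by ``separation`` A."""
    h = separation / 2.0
    return Structure([
        _atom(1, (-h, 0.0, 0.0), -q, radius, name="QM"),
        _atom(2, (+h, 0.0, 0.0), +q, radius, name="QP"),
    ], label="dipole")


def make_charged_patch(n_atoms: int = 18, patch_charge: float = 3.0, *,
                       spacing: float = 3.0, radius: float = 2.0,
                       seed: int = 0) -> tuple[Structure, np.ndarray]:
    """Neutral atom cluster with the charge concentrated on its +x face.

    Atoms sit on a cubic lattice; the layer with the largest x carries
    ``patch_charge`` split equally.  Returns (structure, outward unit
    normal of the charged face) as directional ground truth.
    """
    if n_atoms < 4:
        raise ValueError("need at least 4 atoms")
    m = math.ceil(n_atoms ** (1.0 / 3.0))
    lattice = [(i, j, k) for i in range(m) for j in range(m) for k in range(m)]
    taken = lattice[:n_atoms]
    imax = max(i for i, _, _ in taken)
    face = [t for t in taken if t[0] == imax]
    q_face = patch_charge / len(face)
    center = np.mean([[i, j, k] for i, j, k in taken], axis=0) * spacing
    atoms = []
    for serial, (i, j, k) in enumerate(taken, start=1):
        pos = np.array([i, j, k], dtype=float) * spacing - center
        q = q_face if (i, j, k) in face else 0.0
        atoms.append(_atom(serial, pos, q, radius,
                           name="QP" if q else "C", resnum=serial))
    return Structure(atoms, label=f"patch{patch_charge:+g}"), np.array([1.0, 0.0, 0.0])


def make_pocket(pocket_charge: float = -0.6, *, ring_radius: float = 6.5,
                bead_radius: float = 4.5, charge_radius: float = 1.5
                ) -> tuple[Structure, np.ndarray, np.ndarray]:
    """Charged pocket partially buried in a cup of large neutral beads.

    A cylindrical cup of overlapping coarse-grained beads (vdW radius
    4.5 A, residue-scale) opens toward +x; a partial charge sits at the
    cup bottom.  The accessible nodes nearest the charge see a local
    permittivity around 20 - genuinely "inside" territory for the smooth
    dielectric - while nodes past the mouth sit in nearly bulk water, so
    the Born desolvation term competes with the Coulomb attraction instead
    of being negligible.  Returns (structure, mouth axis unit vector,
    charge position).
    """
    atoms = []
    serial = 1
    for x in (0.0, -3.0, -6.0):
        for t in range(8):
            th = 2.0 * math.pi * t / 8.0
            pos = (x, ring_radius * math.cos(th), ring_radius * math.sin(th))
            atoms.append(_atom(serial, pos, 0.0, bead_radius, resnum=serial))
            serial += 1
    for pos in ((-9.0, 0.0, 0.0), (-9.0, 3.0, 0.0), (-9.0, -3.0, 0.0),
                (-9.0, 0.0, 3.0), (-9.0, 0.0, -3.0)):
        atoms.append(_atom(serial, pos, 0.0, bead_radius, resnum=serial))
        serial += 1
    charge_pos = np.array([-4.5, 0.0, 0.0])
    atoms.append(_atom(serial, charge_pos, pocket_charge, charge_radius,
                       name="Q", resnum=serial))
    return (Structure(atoms, label=f"pocket{pocket_charge:+g}"),
            np.array([1.0, 0.0, 0.0]), charge_pos)


def make_random_cluster(n_atoms: int = 12, seed: int = 0, *,
                        spread: float = 4.0, net_charge: float = 0.0) -> Structure:
    """Seeded random blob of atoms with charges shifted to a target net."""
    if n_atoms < 1:
        raise ValueError("need at least 1 atom")
    rng = np.random.default_rng(seed)
    pos = rng.normal(scale=spread, size=(n_atoms, 3))
    charges = rng.uniform(-0.5, 0.5, size=n_atoms)
    charges += (net_charge - charges.sum()) / n_atoms
    radii = rng.uniform(1.5, 2.2, size=n_atoms)
    atoms = [_atom(i + 1, pos[i], float(charges[i]), float(radii[i]), resnum=i + 1)
             for i in range(n_atoms)]
    return Structure(atoms, label=f"cluster-seed{seed}")


@dataclass
class FixtureSpec:
    """Declarative fixture request (used by the command-line generator)."""

    kind: str
    parameters: dict[str, Any] = field(default_factory=dict)

    _BUILDERS = {
        "born_ion": make_born_ion,
        "dipole": make_dipole,
        "charged_patch": make_charged_patch,
        "pocket": make_pocket,
        "random_cluster": make_random_cluster,
    }

    def build(self):
        """Instantiate the fixture; patch/pocket return tuples with ground
        truth, the rest a bare Structure."""
        if self.kind not in self._BUILDERS:
            raise ValueError(
                f"unknown fixture kind {self.kind!r}; "
                f"known: {sorted(self._BUILDERS)}")
        return self._BUILDERS[self.kind](**self.parameters)
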