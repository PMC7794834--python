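"""Energy-based ranking of candidate ion sites.

Every grid node outside the solute's van der Waals surface is scored with

    G(s) = q_ion * Phi(s) + dG_solv(eps_r(s))

where Phi(s) is the node potential from the modified PBE and eps_r(s) is
the permittivity averaged over the six edge midpoints around the node.
Only negative-G sites are kept, in a min-heap priority queue.  Sites are
popped in order of increasing G and accepted if they (a) do not clash with
any atom (distance >= R_ion + R_atom) and (b) lie more than 6 A from every
previously accepted site.  Accepted sites receive ranks 1, 2, ... up to a
user-set maximum.  Ties in G are broken by lexicographic grid index so the
output is fully deterministic.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, TextIO, Union

import numpy as np

from .constants import kt_kcal
from .dielectric import DielectricField, GaussianParams, dielectric_field
from .grid import GridSpec, build_grid, grid_to_world
from .ions import IonSpec, desolvation_penalty
from .solver import PotentialMap, SolverConfig, solve
from .structure import Atom, Structure

__all__ = [
    "RankedSite",
    "PredictionRun",
    "site_energy",
    "enumerate_candidates",
    "rank_sites",
    "passes_clash",
    "passes_proximity",
    "predict",
    "predict_full",
    "write_sites_tsv",
    "write_sites_pqr",
]

DEFAULT_MIN_SEPARATION = 6.0  # A, mutual site separation


@dataclass(frozen=True)
class RankedSite:
    """One predicted ion position with its energy decomposition."""

    rank: int
    position: np.ndarray  # A
    energy: float  # G(s), kcal/mol
    local_eps: float
    desolv: float  # kcal/mol
    phi: float  # kT/e at the node
    node: tuple[int, int, int]
    neighbors: tuple[tuple[Atom, float], ...] = ()


@dataclass
class PredictionRun:
    """Full pipeline output: sites plus the intermediate fields."""

    sites: list[RankedSite]
    structure: Structure
    ion: IonSpec
    grid: GridSpec
    eps: DielectricField
    potential: PotentialMap
    n_candidates: int
    n_negative: int
    n_clash_rejected: int = 0
    n_proximity_rejected: int = 0


def site_energy(phi_s: float, eps_avg, ion: IonSpec, *, eps_w: float,
                temperature: float = 298.15, include_desolvation: bool = True):
    """G(s) in kcal/mol from the node potential (kT/e) and local eps."""
    g = ion.charge * np.asarray(phi_s, dtype=float) * kt_kcal(temperature)
    if include_desolvation:
        g = g + desolvation_penalty(ion, eps_avg, eps_w)
    return float(g) if np.ndim(g) == 0 else g


def enumerate_candidates(g: GridSpec, s: Structure) -> np.ndarray:
    """Boolean (n,n,n) mask of interior nodes outside the vdW surface.

    A node is a candidate iff its distance to every atom center strictly
    exceeds that atom's vdW radius.  Boundary nodes are never candidates.
    """
    n = g.n
    ax = g.origin[0] + np.arange(n) * g.h
    ay = g.origin[1] + np.arange(n) * g.h
    az = g.origin[2] + np.arange(n) * g.h
    outside = np.ones((n, n, n), dtype=bool)
    for a in s.atoms:
        d2 = ((ax - a.position[0]) ** 2)[:, None, None] \
            + ((ay - a.position[1]) ** 2)[None, :, None] \
            + ((az - a.position[2]) ** 2)[None, None, :]
        outside &= d2 > a.radius**2
    outside[[0, -1], :, :] = False
    outside[:, [0, -1], :] = False
    outside[:, :, [0, -1]] = False
    if not outside.any():
        raise RuntimeError("no exterior grid nodes: grid too small for solute")
    return outside


class SiteQueue:
    """Min-heap over (G, i, j, k); only negative-G entries are stored."""

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, int, int]] = []

    def push(self, energy: float, node: tuple[int, int, int]) -> None:
        if energy < 0.0:
            heapq.heappush(self._heap, (energy, *node))

    def pop(self) -> tuple[float, tuple[int, int, int]]:
        e, i, j, k = heapq.heappop(self._heap)
        return e, (i, j, k)

    def __len__(self) -> int:
        return len(self._heap)

    def __bool__(self) -> bool:
        return bool(self._heap)


def rank_sites(energies: Mapping[tuple[int, int, int], float]) -> SiteQueue:
    """Load candidate energies into the priority queue (negatives only)."""
    q = SiteQueue()
    for node, e in energies.items():
        q.push(e, node)
    return q


def passes_clash(site, s: Structure, ion: IonSpec) -> bool:
    """True iff the site clears R_ion + R_atom from every atom (>=)."""
    d = np.linalg.norm(s.positions - np.asarray(site, dtype=float), axis=1)
    return bool(np.all(d >= ion.clash_radius + s.radii))


def passes_proximity(site, accepted: Iterable, min_sep: float = DEFAULT_MIN_SEPARATION) -> bool:
    """True iff the site is strictly farther than ``min_sep`` from each
    accepted site."""
    site = np.asarray(site, dtype=float)
    for other in accepted:
        if np.linalg.norm(site - np.asarray(other, dtype=float)) <= min_sep:
            return False
    return True


def _neighbor_atoms(site, s: Structure, ion: IonSpec, margin: float
                    ) -> tuple[tuple[Atom, float], ...]:
    d = np.linalg.norm(s.positions - site, axis=1)
    cut = ion.clash_radius + s.radii + margin
    order = np.argsort(d, kind="stable")
    return tuple((s.atoms[i], float(d[i])) for i in order if d[i] <= cut[i])


def predict_full(s: Structure, ion: IonSpec, n_max: int = 10, *,
                 scale: float = 2.0, perfil: float = 70.0,
                 params: Optional[GaussianParams] = None,
                 cfg: Optional[SolverConfig] = None,
                 min_separation: float = DEFAULT_MIN_SEPARATION,
                 include_desolvation: bool = True,
                 neighbor_margin: float = 2.0,
                 grid: Optional[GridSpec] = None) -> PredictionRun:
    """Run the whole pipeline and return sites plus intermediates.

    Steps: grid construction, Gaussian dielectric, modified-PBE solve,
    per-candidate G(s), priority queue, pop with clash and proximity
    filters.  ``include_desolvation=False`` drops the Born term from G(s)
    (the mobile-ion accessibility in the PBE is unaffected); used to probe
    how much the desolvation penalty moves the predictions.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    params = params or GaussianParams()
    cfg = cfg or SolverConfig()
    g = grid or build_grid(s, scale=scale, perfil=perfil)
    eps = dielectric_field(g, s, params)
    pm = solve(s, g, eps, cfg)
    if not pm.converged:
        warnings.warn("ranking a non-converged potential map", RuntimeWarning,
                      stacklevel=2)

    mask = enumerate_candidates(g, s)
    eps_node = eps.node_average()
    energy = site_energy(pm.phi, eps_node, ion, eps_w=params.eps_w,
                         temperature=cfg.temperature,
                         include_desolvation=include_desolvation)

    queue = SiteQueue()
    nodes = np.argwhere(mask & (energy < 0.0))
    # lexicographic push order is irrelevant to heap semantics; the heap
    # tuples themselves carry the tie-break
    for i, j, k in nodes:
        queue.push(float(energy[i, j, k]), (int(i), int(j), int(k)))
    n_negative = len(queue)

    sites: list[RankedSite] = []
    accepted_pos: list[np.ndarray] = []
    n_clash = n_prox = 0
    while queue and len(sites) < n_max:
        e, node = queue.pop()
        pos = grid_to_world(g, node)
        if not passes_clash(pos, s, ion):
            n_clash += 1
            continue
        if not passes_proximity(pos, accepted_pos, min_sep=min_separation):
            n_prox += 1
            continue
        eps_here = float(eps_node[node])
        sites.append(RankedSite(
            rank=len(sites) + 1,
            position=pos,
            energy=e,
            local_eps=eps_here,
            desolv=float(desolvation_penalty(ion, eps_here, params.eps_w)),
            phi=float(pm.phi[node]),
            node=node,
            neighbors=_neighbor_atoms(pos, s, ion, neighbor_margin),
        ))
        accepted_pos.append(pos)
    return PredictionRun(
        sites=sites, structure=s, ion=ion, grid=g, eps=eps, potential=pm,
        n_candidates=int(mask.sum()), n_negative=n_negative,
        n_clash_rejected=n_clash, n_proximity_rejected=n_prox)


def predict(s: Structure, ion: IonSpec, n_max: int = 10, **kwargs) -> list[RankedSite]:
    """Predict up to ``n_max`` surface ion sites; see :func:`predict_full`."""
    return predict_full(s, ion, n_max, **kwargs).sites


def write_sites_tsv(sites: Iterable[RankedSite], dest: Union[str, Path, TextIO],
                    header_lines: Iterable[str] = ()) -> None:
    """Tab-separated site table with the manifest as # comment lines."""
    if isinstance(dest, (str, Path)):
        with Path(dest).open("w") as fh:
            write_sites_tsv(sites, fh, header_lines=header_lines)
        return
    for line in header_lines:
        dest.write(f"# {line}\n")
    dest.write("rank\tx\ty\tz\tG_kcal\tlocal_eps\tdesolv_kcal\tphi_kT\tneighbors\n")
    for s in sites:
        nb = ";".join(f"{a.name}/{a.residue_name}{a.residue_number}:{d:.2f}"
                      for a, d in s.neighbors)
        x, y, z = s.position
        dest.write(f"{s.rank}\t{x:.3f}\t{y:.3f}\t{z:.3f}\t{s.energy:.4f}\t"
                   f"{s.local_eps:.3f}\t{s.desolv:.4f}\t{s.phi:.4f}\t{nb}\n")


def write_sites_pqr(sites: Iterable[RankedSite], ion: IonSpec,
                    dest: Union[str, Path, TextIO],
                    remarks: Iterable[str] = ()) -> None:
    """HETATM records (one per site) loadable in molecular viewers."""
    if isinstance(dest, (str, Path)):
        with Path(dest).open("w") as fh:
            write_sites_pqr(sites, ion, fh, remarks=remarks)
        return
    for r in remarks:
        dest.write(f"REMARK {r}\n")
    name = ion.species[:4]
    for s in sites:
        x, y, z = s.position
        dest.write(
            f"HETATM {s.rank:>5d} {name:<4s} ION  {s.rank:>4d} "
            f"{x:10.3f} {y:10.3f} {z:10.3f} {float(ion.valence):8.4f} "
            f"{ion.clash_radius:7.4f}\n")
    dest.write("END\n")
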