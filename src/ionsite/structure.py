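"""PQR structure reading, writing and preprocessing.

PQR is the PDB-like format in which the occupancy and B-factor columns are
replaced by the per-atom partial charge (e) and van der Waals radius (A).
Emitters in the wild disagree about column widths and whether a chain ID is
present, so the parser follows the robust convention: take the last five
whitespace-separated numeric tokens of every ATOM/HETATM record as
x, y, z, charge, radius.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, TextIO, Union

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "PQRParseError",
    "EmptyStructureError",
    "read_pqr",
    "write_pqr",
    "strip_hetero",
    "net_charge",
]


class PQRParseError(ValueError):
    """A malformed ATOM/HETATM record; message carries the line number."""


class EmptyStructureError(ValueError):
    """A structure with zero atoms where at least one is required."""


@dataclass(frozen=True)
class Atom:
    """One solute atom: position (A), partial charge (e), vdW radius (A)."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray  # shape (3,), Angstrom
    charge: float  # elementary charges
    radius: float  # Angstrom
    record: str = "ATOM"  # "ATOM" or "HETATM"

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.radius > 0:
            raise ValueError(f"atom {self.serial}: radius must be positive, got {self.radius}")


@dataclass
class Structure:
    """An ordered atom collection (the solute charge distribution)."""

    atoms: list[Atom]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise EmptyStructureError(f"structure {self.label!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    # cached array views -------------------------------------------------
    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of atom centers, A."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        """(N,) array of partial charges, e."""
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        """(N,) array of vdW radii, A."""
        return np.array([a.radius for a in self.atoms], dtype=float)

    def bounds(self, include_radii: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (lo, hi); radius-inclusive by default."""
        pos = self.positions
        if include_radii:
            r = self.radii[:, None]
            return (pos - r).min(axis=0), (pos + r).max(axis=0)
        return pos.min(axis=0), pos.max(axis=0)


def _parse_record(line: str, lineno: int) -> Atom:
    tokens = line.split()
    record = tokens[0]
    if len(tokens) < 7:
        raise PQRParseError(f"line {lineno}: too few columns in {record} record")
    try:
        x, y, z, q, r = (float(t) for t in tokens[-5:])
    except ValueError as exc:
        raise PQRParseError(f"line {lineno}: non-numeric field in {record} record: {exc}") from None
    # tokens between the record type and the trailing numerics carry the
    # identifiers; chain ID is optional and detected by token count.
    head = tokens[1:-5]
    serial = 0
    name = resname = chain = ""
    resnum = 0
    try:
        if head:
            serial = int(head[0])
        if len(head) >= 2:
            name = head[1]
        if len(head) >= 3:
            resname = head[2]
        if len(head) == 4:
            resnum = int(head[3])
        elif len(head) >= 5:
            chain = head[3]
            resnum = int(head[4])
    except ValueError as exc:
        raise PQRParseError(f"line {lineno}: bad identifier field: {exc}") from None
    try:
        return Atom(serial, name, resname, chain, resnum,
                    np.array([x, y, z]), q, r, record=record)
    except ValueError as exc:
        raise PQRParseError(f"line {lineno}: {exc}") from None


def read_pqr(source: Union[str, Path, TextIO], label: str = "") -> Structure:
    """Parse a PQR file or text stream into a :class:`Structure`.

    Both ATOM and HETATM records are kept (use :func:`strip_hetero` to drop
    hetero atoms).  Raises :class:`PQRParseError` on a malformed record and
    :class:`EmptyStructureError` if no records are found.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        with path.open() as fh:
            struct = read_pqr(fh, label=label or path.stem)
        return struct
    atoms: list[Atom] = []
    for lineno, line in enumerate(source, start=1):
        if line.startswith(("ATOM", "HETATM")):
            atoms.append(_parse_record(line, lineno))
    if not atoms:
        raise EmptyStructureError(f"no ATOM/HETATM records found in {label!r}")
    return Structure(atoms, label=label)


def write_pqr(s: Structure, dest: Union[str, Path, TextIO],
              remarks: Iterable[str] = ()) -> None:
    """Write a Structure as whitespace-delimited PQR."""
    if isinstance(dest, (str, Path)):
        with Path(dest).open("w") as fh:
            write_pqr(s, fh, remarks=remarks)
        return
    for r in remarks:
        dest.write(f"REMARK {r}\n")
    for a in s.atoms:
        chain = f" {a.chain_id}" if a.chain_id else ""
        x, y, z = a.position
        dest.write(
            f"{a.record:<6s} {a.serial:>5d} {a.name:<4s} {a.residue_name:<4s}"
            f"{chain} {a.residue_number:>4d} "
            f"{x:12.6f} {y:12.6f} {z:12.6f} {a.charge:10.6f} {a.radius:9.6f}\n"
        )
    dest.write("END\n")


def pqr_string(s: Structure, remarks: Iterable[str] = ()) -> str:
    buf = io.StringIO()
    write_pqr(s, buf, remarks=remarks)
    return buf.getvalue()


def strip_hetero(s: Structure) -> Structure:
    """Drop HETATM records (ions and other hetero atoms); input unmodified.

    Idempotent.  Raises :class:`EmptyStructureError` if nothing remains.
    """
    kept = [a for a in s.atoms if a.record == "ATOM"]
    if not kept:
        raise EmptyStructureError(
            f"structure {s.label!r} contains only HETATM records")
    return Structure(list(kept), label=s.label)


def net_charge(s: Structure) -> float:
    """Total solute charge, e."""
    return float(s.charges.sum())
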