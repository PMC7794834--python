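"""Distance metrics against reference (experimentally determined) ion
positions.

Two headline quantities: the rank-1 distance (how far the most confident
prediction lands from the nearest reference ion) and D_min (the shortest
distance between any of the top-k predictions, k = 10 by default, and any
reference position, regardless of rank).  When several reference ions
surround the same solute, each metric uses the reference closest to the
prediction under consideration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .ranking import RankedSite
from .structure import read_pqr

__all__ = [
    "EvaluationResult",
    "rank1_distance",
    "d_min",
    "best_of_n",
    "evaluate",
    "read_reference_positions",
]

_Positions = Union[Sequence, np.ndarray]


def _as_positions(pred) -> np.ndarray:
    """Accept RankedSite lists or bare coordinate arrays."""
    if len(pred) == 0:
        return np.zeros((0, 3))
    rows = [p.position if isinstance(p, RankedSite) else np.asarray(p, float)
            for p in pred]
    return np.vstack(rows)


@dataclass
class EvaluationResult:
    """Metrics for one prediction run against one reference set."""

    rank1_distance: float  # A
    d_min: float  # A
    matched_rank: int  # rank achieving d_min (1-based)
    #: per reference position: (position, best rank within top-k, distance)
    per_experimental: list[tuple[np.ndarray, int, float]]


def rank1_distance(pred, refs: _Positions) -> float:
    """Distance from the rank-1 site to the nearest reference position, A.

    An empty prediction yields NaN (with a warning), never a silent drop.
    """
    refs = np.atleast_2d(np.asarray(refs, dtype=float))
    if refs.size == 0:
        raise ValueError("reference position list is empty")
    p = _as_positions(pred)
    if len(p) == 0:
        warnings.warn("empty prediction list: rank-1 distance undefined",
                      RuntimeWarning, stacklevel=2)
        return math.nan
    return float(np.linalg.norm(refs - p[0], axis=1).min())


def d_min(pred, refs: _Positions, top_k: int = 10) -> tuple[float, int]:
    """Minimum distance between the top-k predictions and any reference.

    Returns (distance, matched_rank).  top_k=1 reduces to the rank-1
    distance.  Empty predictions give (NaN, 0) with a warning.
    """
    refs = np.atleast_2d(np.asarray(refs, dtype=float))
    if refs.size == 0:
        raise ValueError("reference position list is empty")
    p = _as_positions(pred)[:top_k]
    if len(p) == 0:
        warnings.warn("empty prediction list: D_min undefined",
                      RuntimeWarning, stacklevel=2)
        return math.nan, 0
    d = np.linalg.norm(p[:, None, :] - refs[None, :, :], axis=2)
    flat = int(np.argmin(d))
    row = flat // d.shape[1]
    return float(d.flat[flat]), row + 1


def best_of_n(pred_a, pred_b, refs: _Positions, n: int) -> tuple[float, float]:
    """Best-within-first-n comparison of two methods.

    For each method, the minimum distance to any reference among its first
    ``n`` outputs (a method with fewer than n outputs uses all it has).
    This mirrors comparing an unranked placer that drops N neutralizing
    ions against the top-N ranked predictions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return d_min(pred_a, refs, top_k=n)[0], d_min(pred_b, refs, top_k=n)[0]


def evaluate(pred, refs: _Positions, top_k: int = 10) -> EvaluationResult:
    """Full evaluation record, including per-reference best ranks."""
    refs = np.atleast_2d(np.asarray(refs, dtype=float))
    r1 = rank1_distance(pred, refs)
    dm, matched = d_min(pred, refs, top_k=top_k)
    p = _as_positions(pred)[:top_k]
    per = []
    for ref in refs:
        if len(p) == 0:
            per.append((ref, 0, math.nan))
            continue
        d = np.linalg.norm(p - ref, axis=1)
        best = int(np.argmin(d))
        per.append((ref, best + 1, float(d[best])))
    return EvaluationResult(rank1_distance=r1, d_min=dm,
                            matched_rank=matched, per_experimental=per)


def read_reference_positions(path: Union[str, Path]) -> np.ndarray:
    """Reference ion positions from a 3-column table or PQR/PDB HETATMs."""
    path = Path(path)
    text = path.read_text()
    if any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        s = read_pqr(path)
        het = [a.position for a in s.atoms if a.record == "HETATM"]
        if not het:
            raise ValueError(f"no HETATM reference records in {path}")
        return np.vstack(het)
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        rows.append([float(v) for v in parts[:3]])
    if not rows:
        raise ValueError(f"no reference positions in {path}")
    return np.asarray(rows)
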