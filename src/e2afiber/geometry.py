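"""Deterministic local geometry of the extended two-angle model.

A fiber is grown linker by linker.  The state between two nucleosomes is a
:class:`ChainFrame`: the exit point of the previous nucleosome, the unit
tangent of the outgoing linker and a unit normal that carries the dihedral
reference.  One :func:`step_geometry` call advances along the linker,
places the next nucleosome (opening angle ``alpha`` between the in- and
outgoing strand, dihedral ``beta`` about the incoming linker, pitch offset
``d`` between entry and exit point along the nucleosome axis) and returns
the new frame.

Excluded volume is handled with spherical sites on a uniform grid
(cell list): one sphere of the nucleosome radius per nucleosome plus one
sphere of the DNA radius per naked-DNA path vertex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ChainFrame",
    "NucleosomeStep",
    "step_geometry",
    "CellList",
    "pair_contact_distance",
]

_TOL = 1e-9


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _TOL:
        raise ValueError("cannot normalize near-zero vector")
    return v / n


@dataclass(frozen=True)
class ChainFrame:
    """Orthonormal chain state: exit point, outgoing tangent, normal."""

    point: np.ndarray
    tangent: np.ndarray
    normal: np.ndarray

    def validate(self) -> "ChainFrame":
        t, n = np.asarray(self.tangent, float), np.asarray(self.normal, float)
        if (
            abs(np.linalg.norm(t) - 1) > 1e-7
            or abs(np.linalg.norm(n) - 1) > 1e-7
            or abs(float(t @ n)) > 1e-7
        ):
            raise ValueError("frame is not orthonormal")
        return self

    @staticmethod
    def standard(point=(0.0, 0.0, 0.0)) -> "ChainFrame":
        return ChainFrame(
            np.asarray(point, float),
            np.array([0.0, 0.0, 1.0]),
            np.array([1.0, 0.0, 0.0]),
        )


@dataclass(frozen=True)
class NucleosomeStep:
    """Result of one two-angle step: the placed nucleosome and next frame."""

    center: np.ndarray
    entry: np.ndarray
    exit: np.ndarray
    axis: np.ndarray  # nucleosome (cylinder) axis, unit
    tangent_in: np.ndarray
    tangent_out: np.ndarray
    frame: ChainFrame  # state for the next linker


def step_geometry(
    frame: ChainFrame,
    alpha: float,
    beta: float,
    linker_length_nm: float,
    pitch_d_nm: float = 0.0,
) -> NucleosomeStep:
    """Advance one linker + nucleosome from ``frame``.

    The incoming linker of length ``linker_length_nm`` runs along
    ``frame.tangent`` to the entry point.  The outgoing strand leaves so
    that the two strands subtend the opening angle ``alpha`` at the
    nucleosome (alpha = pi is straight-through) with the bending plane
    rotated by the dihedral ``beta`` about the incoming tangent.  Entry
    and exit point are offset by ``pitch_d_nm`` along the nucleosome axis
    (normal of the in/out plane); the center sits midway.

    Deterministic and frame-covariant: rotating the input frame rotates
    every output by the same rotation.
    """
    frame.validate()
    if linker_length_nm <= 0:
        raise ValueError("linker_length_nm must be > 0")
    t_in = frame.tangent
    n = frame.normal
    b = np.cross(t_in, n)
    entry = frame.point + linker_length_nm * t_in
    theta = math.pi - alpha  # deflection of the tangent
    t_out = (
        math.cos(theta) * t_in
        + math.sin(theta) * (math.cos(beta) * n + math.sin(beta) * b)
    )
    t_out = _unit(t_out)
    cross = np.cross(t_in, t_out)
    if np.linalg.norm(cross) < 1e-12:
        axis = n  # straight-through: in/out plane degenerate
    else:
        axis = _unit(cross)
    exit_p = entry + pitch_d_nm * axis
    center = 0.5 * (entry + exit_p)
    # transport the normal: project the old one perpendicular to t_out
    n_new = n - (n @ t_out) * t_out
    if np.linalg.norm(n_new) < 1e-9:
        n_new = np.cross(t_out, b)
    n_new = _unit(n_new)
    return NucleosomeStep(
        center=center,
        entry=entry,
        exit=exit_p,
        axis=axis,
        tangent_in=t_in,
        tangent_out=t_out,
        frame=ChainFrame(exit_p, t_out, n_new),
    )


# --------------------------------------------------------------------------
# Excluded volume


def pair_contact_distance(r1: float, r2: float) -> float:
    return r1 + r2


class CellList:
    """Uniform-grid spatial hash for incremental clash queries.

    Sites are spheres ``(position, radius, genomic_bp)``.  A candidate
    clashes when its center lies closer than the sum of radii to any
    stored site whose genomic coordinate differs by at least
    ``min_separation_bp`` (bonded neighbours are not self-clashes).
    """

    def __init__(self, cell_size_nm: float):
        if cell_size_nm <= 0:
            raise ValueError("cell_size_nm must be > 0")
        self.cell = float(cell_size_nm)
        self._cells: dict[tuple, list[int]] = {}
        self._pos: list[np.ndarray] = []
        self._rad: list[float] = []
        self._bp: list[float] = []

    def __len__(self) -> int:
        return len(self._pos)

    def _key(self, p) -> tuple:
        c = self.cell
        return (int(math.floor(p[0] / c)), int(math.floor(p[1] / c)), int(math.floor(p[2] / c)))

    def add(self, pos: np.ndarray, radius: float, genomic_bp: float) -> None:
        idx = len(self._pos)
        self._pos.append(np.asarray(pos, float))
        self._rad.append(float(radius))
        self._bp.append(float(genomic_bp))
        self._cells.setdefault(self._key(pos), []).append(idx)

    def pop_to(self, n: int) -> None:
        """Remove all sites with index >= n (rollback support)."""
        for idx in range(len(self._pos) - 1, n - 1, -1):
            key = self._key(self._pos[idx])
            self._cells[key].remove(idx)
            if not self._cells[key]:
                del self._cells[key]
        del self._pos[n:]
        del self._rad[n:]
        del self._bp[n:]

    def clashes(
        self,
        pos: np.ndarray,
        radius: float,
        genomic_bp: float,
        min_separation_bp: float,
    ) -> bool:
        kx, ky, kz = self._key(pos)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for i in self._cells.get((kx + dx, ky + dy, kz + dz), ()):
                        if abs(self._bp[i] - genomic_bp) < min_separation_bp:
                            continue
                        d = self._pos[i] - pos
                        lim = self._rad[i] + radius
                        if float(d @ d) < lim * lim:
                            return True
        return False


def excluded_volume_clash(
    existing_pos: Sequence[np.ndarray],
    existing_rad: Sequence[float],
    existing_bp: Sequence[float],
    cand_pos: Sequence[np.ndarray],
    cand_rad: Sequence[float],
    cand_bp: Sequence[float],
    min_separation_bp: float = 0.0,
    cell_size_nm: Optional[float] = None,
) -> bool:
    """Sphere-set overlap test between a fiber prefix and a candidate.

    Symmetric in pair order; exact (no tolerance beyond float math).
    """
    if len(existing_pos) == 0 or len(cand_pos) == 0:
        return False
    if cell_size_nm is None:
        cell_size_nm = 2.0 * max(max(existing_rad), max(cand_rad))
    cl = CellList(cell_size_nm)
    for p, r, g in zip(existing_pos, existing_rad, existing_bp):
        cl.add(p, r, g)
    for p, r, g in zip(cand_pos, cand_rad, cand_bp):
        if cl.clashes(p, r, g, min_separation_bp):
            return True
    return False
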