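"""Deterministic synthetic conformations and brute-force oracles.

Small fixtures with analytically known pair-distance multisets, contact
sets and stiffness, used by the test-suite of every analysis module;
and the O(N^2) reference implementations the fast paths are checked
against.  All fixtures are generated programmatically -- nothing is
read from disk.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .fiber import DefectMask, FiberConformation, REGULAR
from .params import E2AParams, default_params

__all__ = ["fixture_fiber", "brute_force_pairs", "brute_force_contacts"]


def _as_fiber(points: np.ndarray, params: E2AParams) -> FiberConformation:
    """Wrap labelled points as a minimal fiber (one point per repeat)."""
    n = len(points)
    t = np.zeros((n, 3))
    t[:, 2] = 1.0
    ax = np.zeros((n, 3))
    ax[:, 0] = 1.0
    return FiberConformation(
        params=params,
        genomic_index=np.arange(n, dtype=np.int64),
        centers=np.asarray(points, float),
        tangents_in=t,
        tangents_out=t.copy(),
        axes=ax,
        entries=np.asarray(points, float).copy(),
        exits=np.asarray(points, float).copy(),
        defect_mask=DefectMask(np.full(n, REGULAR, dtype=np.int8)),
        genomic_length_bp=n * params.nrl_bp,
    )


def fixture_fiber(
    kind: str,
    n: int,
    seed: int = 0,
    spacing_nm: float = 20.0,
    helix_radius_nm: float = 15.0,
    helix_pitch_nm: float = 10.0,
    helix_turn_rad: float = math.pi / 4,
    hairpin_gap_nm: float = 30.0,
    gas_radius_nm: float = 40.0,
    params: Optional[E2AParams] = None,
) -> FiberConformation:
    """Deterministic small conformations with known statistics.

    kinds:
      - ``rod``: collinear points; pair distances are exact multiples of
        ``spacing_nm``.
      - ``helix``: regular helix (radius, per-step turn, per-step rise);
        zero variance in every r_Delta.
      - ``hairpin``: two antiparallel rods joined at a turn; the two
        strands face each other across ``hairpin_gap_nm``.
      - ``random_gas``: uniform points in a sphere of ``gas_radius_nm``
        (ideal-gas reference, g(r) = 1).
    """
    params = params or default_params()
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "rod":
        pts = np.zeros((n, 3))
        pts[:, 2] = np.arange(n) * spacing_nm
    elif kind == "helix":
        k = np.arange(n)
        pts = np.column_stack(
            [
                helix_radius_nm * np.cos(k * helix_turn_rad),
                helix_radius_nm * np.sin(k * helix_turn_rad),
                k * helix_pitch_nm,
            ]
        )
    elif kind == "hairpin":
        half = (n + 1) // 2
        up = np.zeros((half, 3))
        up[:, 2] = np.arange(half) * spacing_nm
        down = np.zeros((n - half, 3))
        down[:, 0] = hairpin_gap_nm
        down[:, 2] = (half - 1 - np.arange(n - half)) * spacing_nm
        pts = np.vstack([up, down])
    elif kind == "random_gas":
        rng = np.random.default_rng(seed)
        pts = []
        while len(pts) < n:
            c = rng.uniform(-gas_radius_nm, gas_radius_nm, size=3)
            if c @ c <= gas_radius_nm**2:
                pts.append(c)
        pts = np.asarray(pts)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return _as_fiber(pts, params)


def brute_force_pairs(points: np.ndarray) -> np.ndarray:
    """Exact O(N^2) multiset of pair distances, sorted ascending."""
    pts = np.asarray(points, float)
    n = len(pts)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            out.append(float(np.linalg.norm(pts[j] - pts[i])))
    return np.sort(np.asarray(out))


def brute_force_contacts(
    points: np.ndarray,
    genomic_bp: np.ndarray,
    radius_nm: float,
    min_separation_bp: float,
):
    """Exact O(N^2) contact set: sorted (i_bp, j_bp) tuples."""
    pts = np.asarray(points, float)
    bp = np.asarray(genomic_bp, float)
    out = []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if abs(bp[j] - bp[i]) < min_separation_bp:
                continue
            if np.linalg.norm(pts[j] - pts[i]) <= radius_nm:
                out.append((min(bp[i], bp[j]), max(bp[i], bp[j])))
    return sorted(out)
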