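"""Fiber conformation containers: defect masks and grown conformations."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .params import E2AParams

__all__ = ["REGULAR", "LH_SKIP", "NUC_SKIP", "DefectMask", "FiberConformation"]

REGULAR, LH_SKIP, NUC_SKIP = 0, 1, 2


@dataclass(frozen=True)
class DefectMask:
    """Per-repeat defect flags: regular, linker-histone skip, nucleosome skip.

    A run of ``k`` consecutive nucleosome skips leaves a naked-DNA stretch
    of ``k * nrl_bp + linker_bp`` bp (the stretch absorbs the linker that
    would have followed it).
    """

    codes: np.ndarray  # int8, one entry per NRL repeat

    def __post_init__(self):
        object.__setattr__(self, "codes", np.asarray(self.codes, dtype=np.int8))
        if not np.isin(self.codes, [REGULAR, LH_SKIP, NUC_SKIP]).all():
            raise ValueError("defect codes must be 0 (regular), 1 (lh), 2 (nuc)")

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def n_regular(self) -> int:
        return int(np.sum(self.codes == REGULAR))

    @property
    def n_lh_skip(self) -> int:
        return int(np.sum(self.codes == LH_SKIP))

    @property
    def n_nuc_skip(self) -> int:
        return int(np.sum(self.codes == NUC_SKIP))

    def nuc_skip_runs(self) -> List[Tuple[int, int]]:
        """(start_position, run_length) of each maximal nucleosome-skip run."""
        runs = []
        start = None
        for i, c in enumerate(self.codes):
            if c == NUC_SKIP and start is None:
                start = i
            elif c != NUC_SKIP and start is not None:
                runs.append((start, i - start))
                start = None
        if start is not None:
            runs.append((start, len(self.codes) - start))
        return runs

    def naked_stretch_bp(self, run_length: int, params: E2AParams) -> int:
        """Naked-DNA length of a k-skip run: k*NRL + linker."""
        return run_length * params.nrl_bp + params.linker_bp


@dataclass
class FiberConformation:
    """One grown chromatin-fiber conformation.

    Coordinates in nm (float64, right-handed frame); genomic coordinates
    in bp, 0-based.  Nucleosome ``genomic_index`` counts NRL repeats and
    keeps gaps where nucleosomes were skipped; ``dna_points`` are the
    naked-DNA path vertices of the skip stretches.
    """

    params: E2AParams
    genomic_index: np.ndarray  # (N,) int64 repeat index of each nucleosome
    centers: np.ndarray  # (N, 3)
    tangents_in: np.ndarray  # (N, 3) unit
    tangents_out: np.ndarray  # (N, 3) unit
    axes: np.ndarray  # (N, 3) nucleosome axis, unit
    entries: np.ndarray  # (N, 3) DNA entry points
    exits: np.ndarray  # (N, 3) DNA exit points
    defect_mask: DefectMask = None
    genomic_length_bp: int = 0
    dna_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    dna_bp: np.ndarray = field(default_factory=lambda: np.empty((0,)))
    # private record of the random variates used to build the chain
    # (lets Monte Carlo moves rebuild deterministically); not serialized.
    _variates: Optional[list] = None

    @property
    def n_nucleosomes(self) -> int:
        return len(self.centers)

    @property
    def nucleosome_bp(self) -> np.ndarray:
        """Genomic position (bp) of each nucleosome (repeat start)."""
        return self.genomic_index.astype(np.int64) * self.params.nrl_bp

    def end_to_end_nm(self) -> float:
        if self.n_nucleosomes < 2:
            return 0.0
        return float(np.linalg.norm(self.centers[-1] - self.centers[0]))

    def path_sites(self, include_dna: bool = True):
        """All excluded-volume / contact sites of the fiber.

        Returns ``(positions (M,3), radii (M,), genomic_bp (M,))`` for
        nucleosome centers and (optionally) naked-DNA vertices, ordered
        by genomic coordinate.
        """
        p = self.params
        pos = [self.centers]
        rad = [np.full(self.n_nucleosomes, p.nucleosome_radius_nm)]
        bp = [self.nucleosome_bp.astype(float)]
        if include_dna and len(self.dna_points):
            pos.append(self.dna_points)
            rad.append(np.full(len(self.dna_points), p.dna_radius_nm))
            bp.append(self.dna_bp.astype(float))
        pos = np.concatenate(pos)
        rad = np.concatenate(rad)
        bp = np.concatenate(bp)
        order = np.argsort(bp, kind="stable")
        return pos[order], rad[order], bp[order]

    def linker_segments(self):
        """Straight DNA-path segments ``(p0, p1, bp_span, rise_nm_per_bp)``.

        Fiber linkers between consecutive present nucleosomes are single
        effective rods (calibrated effective rise); naked-DNA stretches
        contribute their discretized segments at the B-DNA rise.
        """
        p = self.params
        segs = []
        dna_by_bp = {round(float(b), 6): pt for b, pt in zip(self.dna_bp, self.dna_points)}
        bp_sorted = sorted(dna_by_bp)
        for k in range(self.n_nucleosomes - 1):
            # the linker leaves the wrapped DNA at repeat start + wrapped_bp
            b0 = float(self.nucleosome_bp[k] + p.wrapped_bp)
            b1 = float(self.nucleosome_bp[k + 1])
            inner = [b for b in bp_sorted if b0 < b < b1]
            if not inner:
                seg_bp = b1 - b0
                segs.append((self.exits[k], self.entries[k + 1], seg_bp,
                             float(np.linalg.norm(self.entries[k + 1] - self.exits[k]) / seg_bp)))
            else:
                pts = [self.exits[k]] + [dna_by_bp[b] for b in inner] + [self.entries[k + 1]]
                bps = [b0] + inner + [b1]
                for a, b in zip(range(len(pts) - 1), range(1, len(pts))):
                    span = bps[b] - bps[a]
                    segs.append((pts[a], pts[b], span,
                                 float(np.linalg.norm(pts[b] - pts[a]) / span)))
        return segs

    def validate(self) -> "FiberConformation":
        gi = self.genomic_index
        if len(gi) and np.any(np.diff(gi) < 1):
            raise ValueError("genomic indices must strictly increase")
        if self.defect_mask is not None and len(gi):
            present = np.flatnonzero(self.defect_mask.codes != NUC_SKIP)
            if not np.array_equal(present, gi):
                raise ValueError("index gaps must match nucleosome-skip runs")
        # excluded volume between nucleosomes (non-bonded pairs)
        if self.n_nucleosomes > 1:
            from scipy.spatial import cKDTree

            tree = cKDTree(self.centers)
            lim = self.params.contact_distance_nm
            for i, j in tree.query_pairs(lim):
                sep = abs(float(self.nucleosome_bp[j] - self.nucleosome_bp[i]))
                if sep >= self.params.nrl_bp:
                    raise ValueError(
                        f"nucleosomes {i},{j} closer than contact distance"
                    )
        return self
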