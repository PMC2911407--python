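"""Structural observables of nucleosome point patterns.

Implements the nucleosome pair statistics used to characterize chromatin
nanostructure: the conditional probability p(r) of finding another
nucleosome at distance r, its decomposition into genomic-separation
components r_Delta, the bounded radial pair distribution g(r) inside an
analysis sphere (default radius 40 nm), the isotropic scattering
function S(q) (Fourier transform of g-1), the 2D versions after
orthogonal projection (the observable of localization microscopy), and
peak detection/allocation.

Conventions: histograms use a uniform 0.2 nm bin by default; p(r) is
normalized to unit mass over [0, cutoff]; g is normalized so that 1
equals the mean nucleosome density inside the bounded system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.signal import find_peaks, peak_widths
from scipy.spatial import cKDTree

from .fiber import FiberConformation

__all__ = [
    "DistanceHistogram",
    "RDeltaStats",
    "ScatteringFunction",
    "Peak",
    "PeakAllocation",
    "pair_distances",
    "conditional_probability",
    "r_delta_stats",
    "rdelta_component_histograms",
    "pair_distribution_3d",
    "scattering_function",
    "project_fiber",
    "pair_distribution_2d",
    "detect_peaks",
]

DEFAULT_BIN_NM = 0.2  # spatial binning parameter


# --------------------------------------------------------------------------
# Containers


@dataclass
class DistanceHistogram:
    """Binned pair-distance counts with normalization metadata."""

    edges: np.ndarray  # (nbins+1,), uniform
    counts: np.ndarray  # (nbins,)
    n_pairs_total: int  # pairs with r <= cutoff (the histogram mass)
    n_points_total: int  # reference points contributing
    dimensionality: int  # 2 or 3
    cutoff_nm: float

    def __post_init__(self):
        w = np.diff(self.edges)
        if len(w) and not np.allclose(w, w[0], rtol=1e-9):
            raise ValueError("bin width must be uniform")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def p(self) -> np.ndarray:
        """Normalized conditional probability density p(r): unit mass
        over [0, cutoff]."""
        if self.n_pairs_total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / (self.n_pairs_total * self.bin_width)

    @property
    def mean_density(self) -> float:
        """Mean neighbour density inside the bounded system, per
        reference point (1/nm^dim)."""
        if self.n_points_total == 0:
            return 0.0
        R = self.cutoff_nm
        vol = (4.0 / 3.0) * math.pi * R**3 if self.dimensionality == 3 else math.pi * R**2
        return (2.0 * self.n_pairs_total / self.n_points_total) / vol


@dataclass
class RDeltaStats:
    """Per genomic separation Delta (NRL units): mean, SD, histogram mode."""

    delta: np.ndarray  # (m,) int
    mean_nm: np.ndarray
    sd_nm: np.ndarray
    mode_nm: np.ndarray  # most-frequent value Mf
    count: np.ndarray

    def as_dict(self) -> Dict[int, Tuple[float, float, float, int]]:
        return {
            int(d): (float(m), float(s), float(mf), int(c))
            for d, m, s, mf, c in zip(self.delta, self.mean_nm, self.sd_nm, self.mode_nm, self.count)
        }


@dataclass
class ScatteringFunction:
    q: np.ndarray  # 1/nm
    s: np.ndarray
    cutoff_nm: float
    dimensionality: int = 3


@dataclass
class Peak:
    position_nm: float
    height: float
    left_nm: float
    right_nm: float
    deltas: Tuple[int, ...] = ()


@dataclass
class PeakAllocation:
    peaks: List[Peak] = field(default_factory=list)

    def labelled(self) -> Dict[str, Tuple[int, ...]]:
        """Roman-numeral labels in order of increasing position."""
        roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
        return {roman[i]: p.deltas for i, p in enumerate(self.peaks) if i < len(roman)}


# --------------------------------------------------------------------------
# Pair streaming


def _iter_fibers(obj) -> List[FiberConformation]:
    if isinstance(obj, FiberConformation):
        return [obj]
    return list(obj)


def pair_distances(
    fibers: Union[FiberConformation, Iterable[FiberConformation]],
    cutoff_nm: Optional[float] = None,
    delta_max: Optional[int] = None,
    points_override: Optional[Sequence[np.ndarray]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """All unordered nucleosome pairs as ``(delta, r)`` arrays.

    ``delta`` is the genomic separation in NRL units computed from the
    genomic indices (skipped nucleosomes leave index gaps, so pairs
    spanning a skip carry the true genomic separation).  ``cutoff_nm``
    restricts to spatially close pairs (None = infinity); ``delta_max``
    restricts the genomic separation.  ``points_override`` substitutes
    projected (2D) coordinates for the fibers' 3D centers.
    """
    if cutoff_nm is not None and cutoff_nm <= 0:
        raise ValueError("cutoff_nm must be > 0")
    flist = _iter_fibers(fibers)
    out_d: List[np.ndarray] = []
    out_r: List[np.ndarray] = []
    for fi, f in enumerate(flist):
        pts = np.asarray(points_override[fi]) if points_override is not None else f.centers
        gi = f.genomic_index
        n = len(pts)
        if n < 2:
            continue
        if cutoff_nm is not None:
            pairs = cKDTree(pts).query_pairs(cutoff_nm, output_type="ndarray")
            if len(pairs) == 0:
                continue
            i, j = pairs[:, 0], pairs[:, 1]
            d = np.abs(gi[j] - gi[i])
            r = np.linalg.norm(pts[j] - pts[i], axis=1)
            if delta_max is not None:
                keep = d <= delta_max
                d, r = d[keep], r[keep]
            out_d.append(d)
            out_r.append(r)
        else:
            dmax = delta_max if delta_max is not None else int(gi[-1] - gi[0])
            pos_of = {int(g): k for k, g in enumerate(gi)}
            for dd in range(1, dmax + 1):
                ii = [pos_of[int(g)] for g in gi if int(g) + dd in pos_of]
                if not ii:
                    continue
                jj = [pos_of[int(g) + dd] for g in gi if int(g) + dd in pos_of]
                r = np.linalg.norm(pts[jj] - pts[ii], axis=1)
                out_d.append(np.full(len(r), dd))
                out_r.append(r)
    if not out_d:
        return np.empty(0, dtype=int), np.empty(0)
    return np.concatenate(out_d).astype(int), np.concatenate(out_r)


def conditional_probability(
    distances: np.ndarray,
    cutoff_nm: float,
    bin_nm: float = DEFAULT_BIN_NM,
    n_points_total: int = 0,
    dimensionality: int = 3,
) -> DistanceHistogram:
    """Histogram of pair distances as the conditional probability p(r)."""
    r = np.asarray(distances, float)
    r = r[r <= cutoff_nm]
    nbins = int(math.ceil(cutoff_nm / bin_nm))
    edges = np.arange(nbins + 1) * bin_nm
    counts, _ = np.histogram(r, bins=edges)
    return DistanceHistogram(
        edges=edges,
        counts=counts.astype(float),
        n_pairs_total=int(len(r)),
        n_points_total=int(n_points_total),
        dimensionality=dimensionality,
        cutoff_nm=float(cutoff_nm),
    )


def rdelta_component_histograms(
    deltas: np.ndarray,
    distances: np.ndarray,
    cutoff_nm: float,
    bin_nm: float = DEFAULT_BIN_NM,
) -> Dict[int, np.ndarray]:
    """Per-Delta raw count histograms on the same bins as p(r).

    Their bin-wise sum equals the total histogram exactly (the overall
    p(r) is the superposition of the single r_Delta distributions).
    """
    nbins = int(math.ceil(cutoff_nm / bin_nm))
    edges = np.arange(nbins + 1) * bin_nm
    out = {}
    for d in np.unique(deltas):
        sel = (deltas == d) & (distances <= cutoff_nm)
        counts, _ = np.histogram(distances[sel], bins=edges)
        out[int(d)] = counts.astype(float)
    return out


def r_delta_stats(
    deltas: np.ndarray,
    distances: np.ndarray,
    mode_bin_nm: float = DEFAULT_BIN_NM,
) -> RDeltaStats:
    """Mean, SD and histogram mode of r_Delta for each Delta present.

    The mode (most-frequent value) is the argmax of a fixed-width
    histogram; ties break toward smaller r.
    """
    deltas = np.asarray(deltas)
    distances = np.asarray(distances, float)
    ds = np.unique(deltas)
    mean, sd, mode, cnt = [], [], [], []
    for d in ds:
        r = distances[deltas == d]
        mean.append(r.mean())
        sd.append(r.std(ddof=0))
        nbins = max(1, int(math.ceil(r.max() / mode_bin_nm)))
        counts, edges = np.histogram(r, bins=nbins, range=(0.0, nbins * mode_bin_nm))
        k = int(np.argmax(counts))  # argmax takes the first (smallest-r) tie
        mode.append(0.5 * (edges[k] + edges[k + 1]))
        cnt.append(len(r))
    return RDeltaStats(
        delta=ds.astype(int),
        mean_nm=np.asarray(mean),
        sd_nm=np.asarray(sd),
        mode_nm=np.asarray(mode),
        count=np.asarray(cnt, dtype=int),
    )


# --------------------------------------------------------------------------
# Radial pair distribution and scattering


def pair_distribution_3d(hist: DistanceHistogram) -> Tuple[np.ndarray, np.ndarray]:
    """g(r) on bin centers: p(r)-counts normalized so that 1 equals the
    mean nucleosome density inside the cutoff sphere.

    The r=0 bin is excluded from the returned series (self-pairs are
    never counted; the first bin center is at bin_width/2 > 0).
    """
    if hist.dimensionality != 3:
        raise ValueError("need a 3D histogram")
    if not math.isfinite(hist.cutoff_nm):
        raise ValueError("need a finite cutoff")
    r = hist.centers
    rho = hist.mean_density
    if rho == 0:
        return r, np.zeros_like(r)
    shell = 4.0 * math.pi * r**2 * hist.bin_width
    per_ref = 2.0 * hist.counts / max(hist.n_points_total, 1)
    g = per_ref / (shell * rho)
    return r, g


def pair_distribution_2d(hist: DistanceHistogram) -> Tuple[np.ndarray, np.ndarray]:
    """g2D(r) = p-counts / (2 pi r dr rho_2D) inside the cutoff disk."""
    if hist.dimensionality != 2:
        raise ValueError("need a 2D histogram")
    r = hist.centers
    rho = hist.mean_density
    if rho == 0:
        return r, np.zeros_like(r)
    ring = 2.0 * math.pi * r * hist.bin_width
    per_ref = 2.0 * hist.counts / max(hist.n_points_total, 1)
    return r, per_ref / (ring * rho)


def scattering_function(
    r: np.ndarray,
    g: np.ndarray,
    mean_density: float,
    q_grid: np.ndarray,
    cutoff_nm: Optional[float] = None,
) -> ScatteringFunction:
    """Isotropic scattering function from the pair correlation g-1:

    S(q) = 1 + 4 pi rho \\int_0^R (g(r)-1) r^2 sinc(q r) dr

    evaluated by trapezoidal quadrature on the histogram grid.
    """
    r = np.asarray(r, float)
    g = np.asarray(g, float)
    q = np.asarray(q_grid, float)
    R = float(cutoff_nm if cutoff_nm is not None else r[-1])
    h = g - 1.0
    qr = np.outer(q, r)
    kernel = np.sinc(qr / math.pi)  # sin(x)/x
    integrand = kernel * (h * r**2)
    s = 1.0 + 4.0 * math.pi * mean_density * np.trapezoid(integrand, r, axis=1)
    return ScatteringFunction(q=q, s=s, cutoff_nm=R)


# --------------------------------------------------------------------------
# 2D projection


def project_fiber(
    fiber_or_points: Union[FiberConformation, np.ndarray],
    axis: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Orthogonal projection of nucleosome centers onto the plane normal
    to ``axis`` (default: z; pass ``rng`` for a uniformly random axis).

    Projection can only shorten pair distances, never lengthen them.
    """
    pts = fiber_or_points.centers if isinstance(fiber_or_points, FiberConformation) else np.asarray(fiber_or_points, float)
    if axis is None and rng is None:
        axis = np.array([0.0, 0.0, 1.0])
    elif axis is None:
        v = rng.normal(size=3)
        axis = v / np.linalg.norm(v)
    else:
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
    # orthonormal in-plane basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return np.column_stack([pts @ e1, pts @ e2])


# --------------------------------------------------------------------------
# Peaks


def detect_peaks(
    r: np.ndarray,
    p: np.ndarray,
    component_modes: Optional[Dict[int, float]] = None,
    prominence_frac: float = 0.05,
    smooth_bins: int = 5,
) -> PeakAllocation:
    """Locate dominant maxima of a p(r) series and allocate genomic
    separations to them.

    Each Delta in ``component_modes`` (Delta -> mode of its r_Delta
    component) is assigned to the peak whose half-prominence width
    contains that mode; if none does, to the nearest peak within one
    half-width.  Flat input yields an empty allocation.
    """
    r = np.asarray(r, float)
    p = np.asarray(p, float)
    if len(p) == 0 or np.allclose(p, p[0]):
        return PeakAllocation([])
    y = p
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        y = np.convolve(p, kernel, mode="same")
    prom = prominence_frac * float(y.max())
    idx, props = find_peaks(y, prominence=prom)
    if len(idx) == 0:
        return PeakAllocation([])
    widths, _, lips, rips = peak_widths(y, idx, rel_height=0.5)
    dr = r[1] - r[0] if len(r) > 1 else 1.0
    peaks = [
        Peak(
            position_nm=float(r[i]),
            height=float(y[i]),
            left_nm=float(r[0] + l * dr),
            right_nm=float(r[0] + rr * dr),
        )
        for i, l, rr in zip(idx, lips, rips)
    ]
    peaks.sort(key=lambda pk: pk.position_nm)
    if component_modes:
        alloc: Dict[int, List[int]] = {k: [] for k in range(len(peaks))}
        for d, m in sorted(component_modes.items()):
            inside = [k for k, pk in enumerate(peaks) if pk.left_nm <= m <= pk.right_nm]
            if inside:
                k = min(inside, key=lambda k: abs(peaks[k].position_nm - m))
                alloc[k].append(d)
                continue
            # nearest peak, within twice its half-width (at least 4 nm,
            # so very sharp peaks still collect their components)
            k = min(range(len(peaks)), key=lambda k: abs(peaks[k].position_nm - m))
            hw = 0.5 * (peaks[k].right_nm - peaks[k].left_nm)
            if abs(peaks[k].position_nm - m) <= max(2 * hw, 4.0):
                alloc[k].append(d)
        peaks = [
            Peak(pk.position_nm, pk.height, pk.left_nm, pk.right_nm, tuple(alloc[k]))
            for k, pk in enumerate(peaks)
        ]
    return PeakAllocation(peaks)
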