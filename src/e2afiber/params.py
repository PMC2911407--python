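"""Model parameters of the extended two-angle (E2A) chromatin-fiber model.

The fiber geometry is controlled by per-nucleosome angle distributions
(opening angle alpha between the in- and outgoing linker, dihedral beta
between consecutive linker planes), the linker length, the DNA "pitch"
offset d between the in- and outgoing strand at the nucleosome, and
excluded-volume radii.  Histone-depletion defects are controlled by two
i.i.d. per-repeat skip rates.

Angle/length defaults are calibration constants frozen in
``data/default_params.cfg`` (see :mod:`e2afiber.calibration`); they anchor
the regular fiber to the reference nanostructure statistics (mean adjacent
nucleosome distance 51.0 nm with 0.63 nm spread) and a persistence length
of 280 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import IO, Union

import numpy as np

__all__ = [
    "Fixed",
    "Normal",
    "Uniform",
    "E2AParams",
    "default_params",
    "load_config",
    "save_config",
    "dist_from_spec",
]


# --------------------------------------------------------------------------
# Scalar distributions (the model uses parameter distributions instead of
# interaction potentials; only excluded volume acts as a potential).


@dataclass(frozen=True)
class Fixed:
    """Degenerate distribution: always returns ``value``."""

    value: float

    @property
    def mean(self) -> float:
        return self.value

    @property
    def sd(self) -> float:
        return 0.0

    def sample(self, rng: np.random.Generator, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)

    def to_spec(self) -> str:
        return f"fixed:{self.value!r}"


@dataclass(frozen=True)
class Normal:
    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def mean(self) -> float:
        return self.mu

    @property
    def sd(self) -> float:
        return self.sigma

    def sample(self, rng: np.random.Generator, size=None):
        return rng.normal(self.mu, self.sigma, size=size)

    def to_spec(self) -> str:
        return f"normal:{self.mu!r},{self.sigma!r}"


@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float

    def __post_init__(self):
        if self.hi < self.lo:
            raise ValueError("need hi >= lo")

    @property
    def mean(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def sd(self) -> float:
        return (self.hi - self.lo) / math.sqrt(12.0)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.lo, self.hi, size=size)

    def to_spec(self) -> str:
        return f"uniform:{self.lo!r},{self.hi!r}"


Dist = Union[Fixed, Normal, Uniform]

_DIST_KINDS = {"fixed": Fixed, "normal": Normal, "uniform": Uniform}


def dist_from_spec(spec: str) -> Dist:
    """Parse ``"normal:mu,sigma"`` / ``"uniform:lo,hi"`` / ``"fixed:v"``."""
    kind, _, args = spec.partition(":")
    kind = kind.strip().lower()
    if kind not in _DIST_KINDS:
        raise ValueError(f"unknown distribution kind {kind!r} in {spec!r}")
    vals = [float(v) for v in args.split(",") if v.strip()]
    return _DIST_KINDS[kind](*vals)


# --------------------------------------------------------------------------
# Calibrated default constants.  These are the frozen output of
# ``calibration.calibrate_defaults`` against the reference nanostructure
# anchors; ``data/default_params.cfg`` carries the same numbers.

DEFAULT_ALPHA_MEAN_RAD = 0.690834  # opening angle alpha0 (~39.6 deg)
DEFAULT_ALPHA_SD_RAD = 0.2427
DEFAULT_BETA_MEAN_RAD = 2.242015  # dihedral beta0 (~128.5 deg)
DEFAULT_BETA_SD_RAD = 0.4854
DEFAULT_LINKER_NM = 51.130  # effective linker rod length
DEFAULT_LINKER_SD_NM = 0.630


@dataclass
class E2AParams:
    """All parameters of the extended two-angle chromatin model.

    Lengths are in nm, angles in radians, genomic quantities in bp.
    """

    nrl_bp: int = 196
    wrapped_bp: int = 147
    rise_nm_per_bp: float = 0.34
    alpha_dist: Dist = field(
        default_factory=lambda: Normal(DEFAULT_ALPHA_MEAN_RAD, DEFAULT_ALPHA_SD_RAD)
    )
    beta_dist: Dist = field(
        default_factory=lambda: Normal(DEFAULT_BETA_MEAN_RAD, DEFAULT_BETA_SD_RAD)
    )
    # Effective linker rod between consecutive nucleosome attachment points.
    # This is a calibration constant, NOT linker_bp * rise_nm_per_bp: the
    # reference Delta=1 distance of 51.0 nm fixes an effective geometry that
    # a 49 bp B-DNA rod cannot reach (see docs/methods.md).
    linker_nm: float = DEFAULT_LINKER_NM
    linker_sd_nm: float = DEFAULT_LINKER_SD_NM
    pitch_d_nm: float = 2.7
    nucleosome_radius_nm: float = 5.5
    nucleosome_height_nm: float = 5.5
    dna_radius_nm: float = 1.2
    p_nuc_skip: float = 0.08
    p_lh_skip: float = 0.06
    naked_dna_lp_nm: float = 50.0
    naked_dna_seg_bp: int = 10
    # Linker-histone skip: the entry-exit constraint is released.  alpha is
    # redrawn from a wide uniform opening and up to lh_unwrap_bp_max bp of
    # nucleosomal DNA may unwrap, extending the effective linker.
    lh_alpha_max_rad: float = math.pi
    lh_unwrap_bp_max: float = 80.0
    contact_radius_nm: float = 35.0
    analysis_cutoff_nm: float = 40.0

    @property
    def linker_bp(self) -> int:
        return self.nrl_bp - self.wrapped_bp

    @property
    def effective_rise_nm_per_bp(self) -> float:
        """Effective nm of inter-nucleosome advance per linker bp."""
        return self.linker_nm / self.linker_bp

    @property
    def contact_distance_nm(self) -> float:
        """Center-center contact distance of two nucleosome spheres."""
        return 2.0 * self.nucleosome_radius_nm

    def validate(self) -> "E2AParams":
        if not (0 <= self.p_nuc_skip <= 1 and 0 <= self.p_lh_skip <= 1):
            raise ValueError("skip rates must lie in [0, 1]")
        if self.wrapped_bp >= self.nrl_bp:
            raise ValueError("wrapped_bp must be < nrl_bp")
        for name in (
            "nrl_bp",
            "wrapped_bp",
            "rise_nm_per_bp",
            "linker_nm",
            "nucleosome_radius_nm",
            "nucleosome_height_nm",
            "dna_radius_nm",
            "naked_dna_lp_nm",
            "naked_dna_seg_bp",
            "contact_radius_nm",
            "analysis_cutoff_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.linker_sd_nm < 0 or self.pitch_d_nm < 0:
            raise ValueError("linker_sd_nm and pitch_d_nm must be >= 0")
        return self

    def replace(self, **kw) -> "E2AParams":
        return replace(self, **kw).validate()

    def regular(self) -> "E2AParams":
        """Copy with both skip rates set to zero ('regular' fibers)."""
        return self.replace(p_nuc_skip=0.0, p_lh_skip=0.0)


# --------------------------------------------------------------------------
# Flat key-value config format (one `key = value` per line, '#' comments).

_DIST_FIELDS = ("alpha_dist", "beta_dist")
_INT_FIELDS = ("nrl_bp", "wrapped_bp", "naked_dna_seg_bp")


def save_config(params: E2AParams, dest: Union[str, IO[str]]) -> None:
    lines = ["# E2A model parameters (flat key=value; angles rad, lengths nm)"]
    for f in fields(params):
        v = getattr(params, f.name)
        if f.name in _DIST_FIELDS:
            v = v.to_spec()
        lines.append(f"{f.name} = {v}")
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w") as fh:
            fh.write(text)


def load_config(src: Union[str, IO[str]]) -> E2AParams:
    if hasattr(src, "read"):
        text = src.read()
    else:
        with open(src) as fh:
            text = fh.read()
    known = {f.name for f in fields(E2AParams)}
    kw = {}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {ln}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in known:
            raise ValueError(f"config line {ln}: unknown parameter {key!r}")
        if key in _DIST_FIELDS:
            kw[key] = dist_from_spec(val)
        elif key in _INT_FIELDS:
            kw[key] = int(val)
        else:
            kw[key] = float(val)
    return E2AParams(**kw).validate()


def default_params() -> E2AParams:
    """The shipped, frozen calibrated default parameter set."""
    ref = resources.files("e2afiber.data").joinpath("default_params.cfg")
    with ref.open() as fh:
        return load_config(fh)
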