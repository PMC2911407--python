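"""Ensemble generation: defect sampling, chain growth, Monte Carlo moves.

Conformations are generated by unbiased chain growth: at every repeat
position the local variates (opening angle, dihedral, linker length and,
for defects, the released geometry) are drawn from their parameter
distributions and the step is accepted only if it creates no
excluded-volume clash.  A clash triggers local resampling; if a position
cannot be placed the whole fiber is regrown.  Because every clash-free
chain is drawn from the parameter distributions restricted to the
self-avoiding set, growth already samples the target (athermal)
ensemble; :func:`mc_equilibrate` applies independence-resampling
pivot moves on top, which leave that distribution invariant and serve as
an equilibration cross-check.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
import math
from functools import lru_cache
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from .fiber import LH_SKIP, NUC_SKIP, REGULAR, DefectMask, FiberConformation
from .geometry import CellList, ChainFrame, step_geometry
from .params import E2AParams, default_params, save_config

__all__ = [
    "SimulationConfig",
    "FiberEnsemble",
    "GrowthError",
    "draw_defects",
    "grow_fiber",
    "mc_equilibrate",
    "simulate_ensemble",
]

log = logging.getLogger(__name__)


class GrowthError(RuntimeError):
    """Raised when excluded volume cannot be satisfied while growing."""

    def __init__(self, msg: str, partial_length_bp: int = 0, fiber_index: Optional[int] = None):
        super().__init__(msg)
        self.partial_length_bp = partial_length_bp
        self.fiber_index = fiber_index


@dataclass
class SimulationConfig:
    params: E2AParams = field(default_factory=default_params)
    fiber_length_bp: int = 160_000
    n_fibers: int = 1
    rng_seed: int = 0
    growth_max_retries: int = 200
    max_restarts: int = 20
    mc_moves_per_site: int = 0
    min_ev_separation_bp: Optional[float] = None  # default: 1 NRL

    def __post_init__(self):
        if self.fiber_length_bp < self.params.nrl_bp:
            raise ValueError("fiber_length_bp must be >= one NRL")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")

    @property
    def n_repeats(self) -> int:
        return self.fiber_length_bp // self.params.nrl_bp

    @property
    def ev_min_sep_bp(self) -> float:
        if self.min_ev_separation_bp is not None:
            return self.min_ev_separation_bp
        return float(self.params.nrl_bp)

    def config_hash(self) -> str:
        buf = _io.StringIO()
        save_config(self.params, buf)
        txt = buf.getvalue() + repr(
            (
                self.fiber_length_bp,
                self.n_fibers,
                self.rng_seed,
                self.growth_max_retries,
                self.max_restarts,
                self.mc_moves_per_site,
                self.min_ev_separation_bp,
            )
        )
        return hashlib.sha256(txt.encode()).hexdigest()[:16]


@dataclass
class FiberEnsemble:
    """A reproducible collection of independent fiber conformations."""

    fibers: List[FiberConformation]
    config: SimulationConfig
    sub_seeds: List[tuple]
    retries: List[int]

    def __len__(self) -> int:
        return len(self.fibers)

    def __iter__(self):
        return iter(self.fibers)

    @property
    def provenance(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "rng_seed": self.config.rng_seed,
            "n_fibers": len(self.fibers),
        }


# --------------------------------------------------------------------------
# Defect sampling


def draw_defects(params: E2AParams, n_positions: int, rng: np.random.Generator) -> DefectMask:
    """i.i.d. per-repeat defect assignment.

    Nucleosome skip and linker-histone skip are mutually exclusive at a
    position (a missing octamer implies no histone at all): with
    probability ``p_nuc_skip`` the whole nucleosome is absent, else with
    probability ``p_lh_skip`` only the linker histone is.
    """
    if not (0 <= params.p_nuc_skip <= 1 and 0 <= params.p_lh_skip <= 1):
        raise ValueError("skip rates must lie in [0, 1]")
    u = rng.random(n_positions)
    codes = np.full(n_positions, REGULAR, dtype=np.int8)
    codes[u < params.p_nuc_skip + params.p_lh_skip] = LH_SKIP
    codes[u < params.p_nuc_skip] = NUC_SKIP
    return DefectMask(codes)


# --------------------------------------------------------------------------
# Variates: the random numbers behind one present nucleosome


def _draw_site(params: E2AParams, code: int, rng: np.random.Generator) -> dict:
    if code == LH_SKIP:
        # H1 absent: entry-exit opening released (uniform up to
        # lh_alpha_max_rad), dihedral free, partial DNA unwrapping
        # extends the incoming linker.
        alpha = rng.uniform(params.alpha_dist.mean, params.lh_alpha_max_rad)
        beta = rng.uniform(-math.pi, math.pi)
        unwrap_bp = rng.uniform(0.0, params.lh_unwrap_bp_max)
    else:
        alpha = float(params.alpha_dist.sample(rng))
        beta = float(params.beta_dist.sample(rng))
        unwrap_bp = 0.0
    jitter = rng.normal(0.0, params.linker_sd_nm) if params.linker_sd_nm > 0 else 0.0
    return {"alpha": alpha, "beta": beta, "jitter_nm": jitter, "unwrap_bp": unwrap_bp}


@lru_cache(maxsize=64)
def _wlc_sigma(ratio: float) -> float:
    """Bend scale sigma such that the normalized-sum bend update
    t' = (t + sigma*g)/|..| has exactly <cos theta> = exp(-seg/lp).

    With g a standard 2D Gaussian in the normal plane,
    <cos theta> = E_u~Exp(1)[(1 + 2 sigma^2 u)^(-1/2)].
    """
    from scipy.integrate import quad
    from scipy.optimize import brentq

    target = math.exp(-ratio)

    def mean_cos(sig):
        val, _ = quad(lambda u: math.exp(-u) / math.sqrt(1.0 + 2.0 * sig * sig * u),
                      0.0, 60.0, limit=200)
        return val

    return brentq(lambda s: mean_cos(s) - target, 1e-9, 10.0, xtol=1e-12)


def _draw_wlc(params: E2AParams, n_segs: int, rng: np.random.Generator) -> dict:
    """Bend variates of a worm-like-chain naked-DNA path (unit normals;
    the bend scale sqrt(seg/lp) is applied at build time)."""
    gx = rng.normal(0.0, 1.0, n_segs)
    gy = rng.normal(0.0, 1.0, n_segs)
    return {"gx": gx, "gy": gy}


# --------------------------------------------------------------------------
# Chain assembly


class _Builder:
    """Incremental chain assembly with excluded-volume bookkeeping."""

    def __init__(self, config: SimulationConfig, check_ev: bool = True):
        self.cfg = config
        self.p = config.params
        self.check_ev = check_ev
        self.cell = CellList(max(self.p.contact_distance_nm, 2 * self.p.dna_radius_nm))
        self.frame: Optional[ChainFrame] = None  # exit frame of last element
        self.centers, self.entries, self.exits = [], [], []
        self.axes, self.t_in, self.t_out = [], [], []
        self.gidx: List[int] = []
        self.dna_pts: List[np.ndarray] = []
        self.dna_bp: List[float] = []
        self._commits: List[dict] = []  # pre-commit state, for rollback

    def _checkpoint(self) -> dict:
        return {
            "n_cell": len(self.cell),
            "n_nuc": len(self.centers),
            "n_dna": len(self.dna_pts),
            "frame": self.frame,
        }

    def rollback_last(self) -> None:
        """Undo the most recent committed extension."""
        st = self._commits.pop()
        self.cell.pop_to(st["n_cell"])
        for lst in (self.centers, self.entries, self.exits, self.axes,
                    self.t_in, self.t_out, self.gidx):
            del lst[st["n_nuc"]:]
        del self.dna_pts[st["n_dna"]:]
        del self.dna_bp[st["n_dna"]:]
        self.frame = st["frame"]

    # -- naked DNA -----------------------------------------------------
    def _wlc_path(self, start_frame: ChainFrame, total_bp: float, wlc: dict):
        """Worm-like-chain vertices; returns (points, end ChainFrame)."""
        p = self.p
        n_segs = max(2, int(round(total_bp / p.naked_dna_seg_bp)))
        seg_nm = total_bp * p.rise_nm_per_bp / n_segs
        sigma = _wlc_sigma(round(seg_nm / p.naked_dna_lp_nm, 12))
        t = start_frame.tangent.copy()
        n = start_frame.normal.copy()
        pos = start_frame.point.copy()
        pts = []
        for s in range(n_segs):
            b = np.cross(t, n)
            t = t + sigma * (wlc["gx"][s] * n + wlc["gy"][s] * b)
            t /= np.linalg.norm(t)
            n = n - (n @ t) * t
            n /= np.linalg.norm(n)
            pos = pos + seg_nm * t
            pts.append(pos.copy())
        return pts, ChainFrame(pos, t, n)

    # -- one present nucleosome ---------------------------------------
    def try_extend(self, position: int, pending_skips: int, site: dict, wlc: Optional[dict]) -> bool:
        """Attempt to place the nucleosome of repeat ``position``.

        ``pending_skips`` is the number of nucleosome-skip repeats
        immediately before it (0 for a plain linker step).  Returns True
        and commits on success; leaves the builder untouched on clash.
        """
        p = self.p
        nrl = p.nrl_bp
        bp_here = position * nrl
        linker_len = max(0.1, p.linker_nm + site["jitter_nm"]
                         + site["unwrap_bp"] * p.effective_rise_nm_per_bp)

        new_dna_pts: List[np.ndarray] = []
        new_dna_bp: List[float] = []
        if pending_skips > 0 or (self.frame is None and wlc is not None):
            stretch_bp = pending_skips * nrl + p.linker_bp
            if self.frame is None:
                start = ChainFrame.standard()
                bp0 = bp_here - stretch_bp
            else:
                start = self.frame
                bp0 = self.gidx[-1] * nrl + p.wrapped_bp
            pts, end_frame = self._wlc_path(start, stretch_bp, wlc)
            # last WLC vertex becomes the entry step of the nucleosome
            step_frame = ChainFrame(
                pts[-2] if len(pts) > 1 else start.point,
                end_frame.tangent,
                end_frame.normal,
            )
            seg_nm = stretch_bp * p.rise_nm_per_bp / max(2, int(round(stretch_bp / p.naked_dna_seg_bp)))
            step = step_geometry(step_frame, site["alpha"], site["beta"], seg_nm, p.pitch_d_nm)
            n_pts = len(pts)
            for k, pt in enumerate(pts[:-1]):
                new_dna_pts.append(pt)
                new_dna_bp.append(bp0 + (k + 1) * stretch_bp / n_pts)
        elif self.frame is None:
            # first nucleosome, no leading naked DNA: land its entry at 0
            virt = ChainFrame(
                np.array([0.0, 0.0, -linker_len]),
                np.array([0.0, 0.0, 1.0]),
                np.array([1.0, 0.0, 0.0]),
            )
            step = step_geometry(virt, site["alpha"], site["beta"], linker_len, p.pitch_d_nm)
        else:
            step = step_geometry(self.frame, site["alpha"], site["beta"], linker_len, p.pitch_d_nm)

        if self.check_ev:
            min_sep = self.cfg.ev_min_sep_bp
            if self.cell.clashes(step.center, p.nucleosome_radius_nm, float(bp_here), min_sep):
                return False
            for pt, bpv in zip(new_dna_pts, new_dna_bp):
                if self.cell.clashes(pt, p.dna_radius_nm, bpv, min_sep):
                    return False

        # commit
        self._commits.append(self._checkpoint())
        self.cell.add(step.center, p.nucleosome_radius_nm, float(bp_here))
        for pt, bpv in zip(new_dna_pts, new_dna_bp):
            self.cell.add(pt, p.dna_radius_nm, bpv)
            self.dna_pts.append(pt)
            self.dna_bp.append(bpv)
        self.centers.append(step.center)
        self.entries.append(step.entry)
        self.exits.append(step.exit)
        self.axes.append(step.axis)
        self.t_in.append(step.tangent_in)
        self.t_out.append(step.tangent_out)
        self.gidx.append(position)
        self.frame = step.frame
        return True

    def add_tail(self, n_skips: int, wlc: dict) -> bool:
        """Trailing naked DNA after the last present nucleosome."""
        p = self.p
        stretch_bp = n_skips * p.nrl_bp + p.linker_bp
        start = self.frame if self.frame is not None else ChainFrame.standard()
        bp0 = (self.gidx[-1] * p.nrl_bp + p.wrapped_bp) if self.gidx else 0.0
        pts, end = self._wlc_path(start, stretch_bp, wlc)
        n_pts = len(pts)
        if self.check_ev:
            for k, pt in enumerate(pts):
                if self.cell.clashes(pt, p.dna_radius_nm, bp0 + (k + 1) * stretch_bp / n_pts,
                                     self.cfg.ev_min_sep_bp):
                    return False
        self._commits.append(self._checkpoint())
        for k, pt in enumerate(pts):
            bpv = bp0 + (k + 1) * stretch_bp / n_pts
            self.cell.add(pt, p.dna_radius_nm, bpv)
            self.dna_pts.append(pt)
            self.dna_bp.append(bpv)
        self.frame = end
        return True

    def finish(self, mask: DefectMask, length_bp: int, variates: list) -> FiberConformation:
        centers = np.asarray(self.centers).reshape(-1, 3)
        shift = centers[0].copy() if len(centers) else np.zeros(3)
        fib = FiberConformation(
            params=self.p,
            genomic_index=np.asarray(self.gidx, dtype=np.int64),
            centers=centers - shift,
            tangents_in=np.asarray(self.t_in).reshape(-1, 3),
            tangents_out=np.asarray(self.t_out).reshape(-1, 3),
            axes=np.asarray(self.axes).reshape(-1, 3),
            entries=np.asarray(self.entries).reshape(-1, 3) - shift,
            exits=np.asarray(self.exits).reshape(-1, 3) - shift,
            defect_mask=mask,
            genomic_length_bp=length_bp,
            dna_points=(np.asarray(self.dna_pts).reshape(-1, 3) - shift
                        if self.dna_pts else np.empty((0, 3))),
            dna_bp=np.asarray(self.dna_bp, dtype=float),
            _variates=variates,
        )
        return fib


def _assemble(config: SimulationConfig, mask: DefectMask, variates: list,
              check_ev: bool = True):
    """Rebuild a full chain from stored variates.

    Returns ``(fiber or None, clash_position)``; clash_position is None on
    success.  Bit-identical to the incremental growth path.
    """
    b = _Builder(config, check_ev=check_ev)
    vi = 0
    pending = 0
    for pos, code in enumerate(mask.codes):
        if code == NUC_SKIP:
            pending += 1
            continue
        v = variates[vi]
        ok = b.try_extend(pos, pending, v["site"], v.get("wlc"))
        if not ok:
            return None, pos
        vi += 1
        pending = 0
    if pending:
        v = variates[vi]
        if not b.add_tail(pending, v["wlc"]):
            return None, len(mask.codes)
    return b.finish(mask, config.fiber_length_bp, variates), None


# --------------------------------------------------------------------------
# Growth


def grow_fiber(config: SimulationConfig, rng: np.random.Generator,
               mask: Optional[DefectMask] = None) -> FiberConformation:
    """Grow one clash-free fiber conformation.

    Local clashes are resolved by resampling the offending position up to
    ``growth_max_retries`` times; a stuck fiber is regrown from scratch up
    to ``max_restarts`` times before :class:`GrowthError` is raised.
    """
    p = config.params
    n_rep = config.n_repeats
    fixed_mask = mask
    local_retries = max(1, config.growth_max_retries // 10)
    failed_at = 0
    for restart in range(config.max_restarts + 1):
        m = fixed_mask if fixed_mask is not None else draw_defects(p, n_rep, rng)
        # present positions with their preceding skip-run lengths
        jobs = []  # (position, code, pending_skips)
        pending = 0
        for pos, code in enumerate(m.codes):
            if code == NUC_SKIP:
                pending += 1
            else:
                jobs.append((pos, int(code), pending))
                pending = 0
        tail_skips = pending

        b = _Builder(config)
        variates: list = [None] * len(jobs)
        attempts = [0] * (len(jobs) + 1)
        n_retries = 0
        backtracks = 0
        max_backtracks = config.growth_max_retries * max(1, len(jobs)) // 10
        i = 0
        stuck = False
        while i < len(jobs):
            pos, code, pend = jobs[i]
            site = _draw_site(p, code, rng)
            wlc = None
            if pend > 0:
                stretch_bp = pend * p.nrl_bp + p.linker_bp
                n_segs = max(2, int(round(stretch_bp / p.naked_dna_seg_bp)))
                wlc = _draw_wlc(p, n_segs, rng)
            if b.try_extend(pos, pend, site, wlc):
                variates[i] = {"site": site, "wlc": wlc}
                attempts[i] = 0
                i += 1
                continue
            n_retries += 1
            attempts[i] += 1
            if attempts[i] > local_retries:
                # the clash is usually baked in by the previous draw:
                # undo one committed position and redraw it too
                if i == 0 or backtracks >= max_backtracks:
                    stuck = True
                    failed_at = pos
                    break
                b.rollback_last()
                attempts[i] = 0
                backtracks += 1
                i -= 1
        if not stuck and tail_skips:
            stretch_bp = tail_skips * p.nrl_bp + p.linker_bp
            n_segs = max(2, int(round(stretch_bp / p.naked_dna_seg_bp)))
            ok = False
            for _try in range(config.growth_max_retries + 1):
                wlc = _draw_wlc(p, n_segs, rng)
                if b.add_tail(tail_skips, wlc):
                    variates.append({"site": None, "wlc": wlc})
                    ok = True
                    break
                n_retries += 1
            if not ok:
                stuck = True
                failed_at = len(m.codes)
        if not stuck:
            fib = b.finish(m, config.fiber_length_bp, variates)
            fib.growth_retries = n_retries
            return fib
        log.debug("growth restart %d (stuck at position %s)", restart + 1, failed_at)
    raise GrowthError(
        f"excluded volume unsatisfiable after {config.max_restarts} restarts",
        partial_length_bp=failed_at * p.nrl_bp,
    )


# --------------------------------------------------------------------------
# Monte Carlo


def mc_equilibrate(fiber: FiberConformation, config: SimulationConfig,
                   rng: np.random.Generator, n_moves: Optional[int] = None) -> FiberConformation:
    """Independence-resampling pivot sweep.

    A move redraws the variates of one present position from their prior
    distributions and rigidly rebuilds the chain downstream; it is
    accepted iff the new chain is clash-free.  Proposals do not depend on
    the current state, so detailed balance w.r.t. the growth ensemble
    (parameter distributions restricted to self-avoiding chains) holds.
    With zero moves this is the identity.
    """
    if fiber._variates is None:
        raise ValueError("fiber carries no variate record; regrow it first")
    variates = [dict(v) for v in fiber._variates]
    mask = fiber.defect_mask
    n_sites = len(variates)
    if n_moves is None:
        n_moves = config.mc_moves_per_site * n_sites
    current = fiber
    p = config.params
    present_codes = [c for c in mask.codes if c != NUC_SKIP]
    pendings = []
    pend = 0
    for c in mask.codes:
        if c == NUC_SKIP:
            pend += 1
        else:
            pendings.append(pend)
            pend = 0
    tail = pend
    for _ in range(n_moves):
        k = int(rng.integers(0, n_sites))
        old = variates[k]
        if old["site"] is None:  # trailing naked DNA
            n_segs = len(old["wlc"]["gx"])
            prop = {"site": None, "wlc": _draw_wlc(p, n_segs, rng)}
        else:
            code = present_codes[k] if k < len(present_codes) else REGULAR
            site = _draw_site(p, code, rng)
            wlc = None
            if old.get("wlc") is not None:
                wlc = _draw_wlc(p, len(old["wlc"]["gx"]), rng)
            prop = {"site": site, "wlc": wlc}
        variates[k] = prop
        rebuilt, clash_at = _assemble(config, mask, variates)
        if rebuilt is None:
            variates[k] = old  # reject
        else:
            current = rebuilt
    return current


# --------------------------------------------------------------------------
# Ensembles


def simulate_ensemble(config: SimulationConfig) -> FiberEnsemble:
    """Generate ``n_fibers`` independent fibers, reproducible from the seed."""
    fibers = []
    sub_seeds = []
    retries = []
    for i in range(config.n_fibers):
        seed_key = (config.rng_seed, i)
        rng = np.random.default_rng(seed_key)
        try:
            fib = grow_fiber(config, rng)
        except GrowthError as e:
            e.fiber_index = i
            raise
        if config.mc_moves_per_site > 0:
            fib = mc_equilibrate(fib, config, rng)
        fibers.append(fib)
        sub_seeds.append(seed_key)
        retries.append(getattr(fib, "growth_retries", 0))
        if (i + 1) % 50 == 0 or i + 1 == config.n_fibers:
            log.info("simulated %d/%d fibers", i + 1, config.n_fibers)
    return FiberEnsemble(fibers=fibers, config=config, sub_seeds=sub_seeds, retries=retries)


def equilibration_diagnostic(ensemble: FiberEnsemble) -> dict:
    """Block check: half-ensemble means of R_ee^2 should agree within 1 SE."""
    r2 = np.array([f.end_to_end_nm() ** 2 for f in ensemble.fibers])
    h = len(r2) // 2
    if h < 2:
        return {"equilibrated": True, "drift_se": 0.0}
    a, bvals = r2[:h], r2[h:]
    se = np.sqrt(a.var(ddof=1) / len(a) + bvals.var(ddof=1) / len(bvals))
    drift = abs(a.mean() - bvals.mean())
    return {"equilibrated": bool(drift <= se), "drift_se": float(drift / se) if se else 0.0}
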