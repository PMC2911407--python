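"""File formats: ensemble archives (HDF5), coordinate export (XYZ/PDB),
tab-separated histogram/series output.

Conventions (also recorded in every archive): coordinates in nm,
float64, right-handed frame; genomic coordinates 0-based, bp.  Output
headers carry the seed and config hash so any result is regenerable.
"""

from __future__ import annotations

import io as _io
from typing import Dict, List, Optional, Tuple

import h5py
import numpy as np
import pandas as pd

from .fiber import DefectMask, FiberConformation
from .params import load_config, save_config
from .simulate import FiberEnsemble, SimulationConfig

__all__ = [
    "SCHEMA_VERSION",
    "write_ensemble",
    "read_ensemble",
    "write_conformation_xyz",
    "write_conformation_pdb",
    "read_xyz_points",
    "write_series_tsv",
    "read_series_tsv",
]

SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# Ensemble archive (HDF5)


def write_ensemble(ensemble: FiberEnsemble, path: str) -> None:
    cfg = ensemble.config
    buf = _io.StringIO()
    save_config(cfg.params, buf)
    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = SCHEMA_VERSION
        h5.attrs["coordinate_units"] = "nm"
        h5.attrs["genomic_units"] = "bp, 0-based"
        h5.attrs["params_config"] = buf.getvalue()
        h5.attrs["fiber_length_bp"] = cfg.fiber_length_bp
        h5.attrs["n_fibers"] = len(ensemble.fibers)
        h5.attrs["rng_seed"] = cfg.rng_seed
        h5.attrs["config_hash"] = cfg.config_hash()
        grp = h5.create_group("fibers")
        for k, f in enumerate(ensemble.fibers):
            g = grp.create_group(str(k))
            g.create_dataset("genomic_index", data=f.genomic_index)
            g.create_dataset("centers", data=f.centers)
            g.create_dataset("tangents_in", data=f.tangents_in)
            g.create_dataset("tangents_out", data=f.tangents_out)
            g.create_dataset("axes", data=f.axes)
            g.create_dataset("entries", data=f.entries)
            g.create_dataset("exits", data=f.exits)
            g.create_dataset("defect_codes", data=f.defect_mask.codes)
            g.create_dataset("dna_points", data=f.dna_points)
            g.create_dataset("dna_bp", data=f.dna_bp)
            g.attrs["genomic_length_bp"] = f.genomic_length_bp
            g.attrs["sub_seed"] = repr(ensemble.sub_seeds[k])
            g.attrs["growth_retries"] = ensemble.retries[k]


def read_ensemble(path: str) -> FiberEnsemble:
    with h5py.File(path, "r") as h5:
        version = int(h5.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported archive schema version {version} "
                f"(expected {SCHEMA_VERSION})"
            )
        params = load_config(_io.StringIO(h5.attrs["params_config"]))
        cfg = SimulationConfig(
            params=params,
            fiber_length_bp=int(h5.attrs["fiber_length_bp"]),
            n_fibers=int(h5.attrs["n_fibers"]),
            rng_seed=int(h5.attrs["rng_seed"]),
        )
        fibers = []
        seeds = []
        retries = []
        for k in sorted(h5["fibers"], key=int):
            g = h5["fibers"][k]
            fibers.append(
                FiberConformation(
                    params=params,
                    genomic_index=g["genomic_index"][()],
                    centers=g["centers"][()],
                    tangents_in=g["tangents_in"][()],
                    tangents_out=g["tangents_out"][()],
                    axes=g["axes"][()],
                    entries=g["entries"][()],
                    exits=g["exits"][()],
                    defect_mask=DefectMask(g["defect_codes"][()]),
                    genomic_length_bp=int(g.attrs["genomic_length_bp"]),
                    dna_points=g["dna_points"][()],
                    dna_bp=g["dna_bp"][()],
                )
            )
            seeds.append(g.attrs["sub_seed"])
            retries.append(int(g.attrs["growth_retries"]))
    return FiberEnsemble(fibers=fibers, config=cfg, sub_seeds=seeds, retries=retries)


# --------------------------------------------------------------------------
# Coordinate export


def write_conformation_xyz(
    fiber: FiberConformation,
    path: str,
    include_dna: bool = False,
    comment: str = "",
) -> None:
    """XYZ export: one record per nucleosome center (label NUC, or LHS
    for linker-histone skips), optionally DNA path vertices (DNA)."""
    from .fiber import LH_SKIP

    labels: List[str] = []
    coords: List[np.ndarray] = []
    codes = fiber.defect_mask.codes if fiber.defect_mask is not None else None
    for k in range(fiber.n_nucleosomes):
        code = codes[fiber.genomic_index[k]] if codes is not None else 0
        labels.append("LHS" if code == LH_SKIP else "NUC")
        coords.append(fiber.centers[k])
    if include_dna:
        for pt in fiber.dna_points:
            labels.append("DNA")
            coords.append(pt)
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        fh.write(f"{comment or 'e2afiber conformation (nm)'}\n")
        for lab, c in zip(labels, coords):
            fh.write(f"{lab} {c[0]:.6f} {c[1]:.6f} {c[2]:.6f}\n")


def read_xyz_points(path: str) -> Tuple[List[str], np.ndarray]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise ValueError(f"{path}:1: expected atom count") from None
    labels, pts = [], []
    for ln, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{ln}: expected 'label x y z'")
        labels.append(parts[0])
        pts.append([float(x) for x in parts[1:]])
    if len(pts) != n:
        raise ValueError(f"{path}: promised {n} records, found {len(pts)}")
    return labels, np.asarray(pts)


def write_conformation_pdb(
    fiber: FiberConformation,
    path: str,
    include_dna: bool = False,
) -> None:
    """PDB export (coordinates nm -> Angstrom).

    Nucleosomes are HETATM records named NUC, residue number = genomic
    repeat index; linker-histone skips get occupancy 0.50, regular
    nucleosomes 1.00; naked-DNA vertices are chain B.
    """
    from .fiber import LH_SKIP

    codes = fiber.defect_mask.codes if fiber.defect_mask is not None else None
    with open(path, "w") as fh:
        fh.write("REMARK   1 E2AFIBER CONFORMATION, COORDINATES NM*10 (ANGSTROM)\n")
        serial = 1
        for k in range(fiber.n_nucleosomes):
            gi = int(fiber.genomic_index[k])
            occ = 1.0
            if codes is not None and codes[gi] == LH_SKIP:
                occ = 0.5
            x, y, z = fiber.centers[k] * 10.0
            fh.write(
                f"HETATM{serial:5d}  C   NUC A{gi % 10000:4d}    "
                f"{x:8.2f}{y:8.2f}{z:8.2f}{occ:6.2f}{0.0:6.2f}           C\n"
            )
            serial += 1
        if include_dna:
            for j, pt in enumerate(fiber.dna_points):
                x, y, z = pt * 10.0
                fh.write(
                    f"HETATM{serial:5d}  P   DNA B{j % 10000:4d}    "
                    f"{x:8.2f}{y:8.2f}{z:8.2f}{1.0:6.2f}{0.0:6.2f}           P\n"
                )
                serial += 1
        fh.write("END\n")


# --------------------------------------------------------------------------
# Tab-separated series with '#key=value' metadata header


def write_series_tsv(path: str, columns: Dict[str, np.ndarray],
                     meta: Optional[Dict[str, object]] = None) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"#{k}={v}\n")
        pd.DataFrame(columns).to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_series_tsv(path: str) -> Tuple[pd.DataFrame, Dict[str, str]]:
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                if "=" in line:
                    k, _, v = line[1:].rstrip("\n").partition("=")
                    meta[k.strip()] = v.strip()
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    return df, meta
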