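"""Reading and writing localization tables.

Two on-disk formats are supported: the package's own CSV schema
(particle_id, x_nm, y_nm, [z_nm], sigma_nm, [sigma_z_nm], [true_class])
and Picasso-style HDF5 picked-localization tables (a structured "locs"
dataset with x/y in camera pixels, lpx/lpy uncertainties and a "group"
column identifying the picked particle).  Everything is converted to nm
on load.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .particles import LocalizationSet

logger = logging.getLogger(__name__)

CSV_REQUIRED = ("particle_id", "x_nm", "y_nm", "sigma_nm")


def _frame_to_particles(df: pd.DataFrame):
    particles = []
    labels = []
    has_z = "z_nm" in df.columns
    has_cls = "true_class" in df.columns
    for pid, grp in df.groupby("particle_id", sort=True):
        coords = grp[["x_nm", "y_nm", "z_nm"]].to_numpy() if has_z \
            else grp[["x_nm", "y_nm"]].to_numpy()
        sigma = grp["sigma_nm"].to_numpy()
        sigma_z = grp["sigma_z_nm"].to_numpy() if "sigma_z_nm" in grp else None
        p = LocalizationSet(coords, sigma, sigma_z, particle_id=pid)
        if p.n < 3:
            logger.warning("particle %s has only %d localizations", pid, p.n)
        particles.append(p)
        if has_cls:
            labels.append(int(grp["true_class"].iloc[0]))
    return particles, (np.array(labels) if has_cls else None)


def read_csv(path) -> tuple[list[LocalizationSet], np.ndarray | None]:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty localization table")
    missing = [c for c in CSV_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["sigma_nm"] <= 0).any():
        raise ValueError(f"{path}: non-positive sigma values")
    return _frame_to_particles(df)


def read_picasso_hdf5(path, pixel_nm: float) -> tuple[list[LocalizationSet], None]:
    """Read a Picasso picked-localizations HDF5 file; coordinates and
    lpx/lpy are camera-pixel units and are scaled by ``pixel_nm``."""
    with h5py.File(path, "r") as f:
        if "locs" not in f:
            raise ValueError(f"{path}: no 'locs' dataset")
        locs = f["locs"][...]
    names = locs.dtype.names or ()
    for c in ("x", "y", "lpx", "lpy"):
        if c not in names:
            raise ValueError(f"{path}: missing field {c!r}")
    if len(locs) == 0:
        raise ValueError(f"{path}: empty localization table")
    group = locs["group"] if "group" in names else np.zeros(len(locs), int)
    sigma_px = 0.5 * (locs["lpx"] + locs["lpy"])
    if (sigma_px <= 0).any():
        raise ValueError(f"{path}: non-positive localization precision")
    df = pd.DataFrame({
        "particle_id": group.astype(int),
        "x_nm": locs["x"] * pixel_nm,
        "y_nm": locs["y"] * pixel_nm,
        "sigma_nm": sigma_px * pixel_nm,
    })
    if "z" in names:  # Picasso stores z in nm already
        df["z_nm"] = locs["z"]
        df["sigma_z_nm"] = (locs["lpz"] if "lpz" in names
                            else sigma_px * pixel_nm)
    particles, _ = _frame_to_particles(df)
    return particles, None


def read_localizations(path, fmt: str | None = None,
                       pixel_nm: float = 130.0):
    """Load particles from CSV or Picasso HDF5.

    Returns (particles, ground-truth labels or None).  ``fmt`` is
    inferred from the extension when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "picasso-hdf5" if path.suffix in (".h5", ".hdf5") else "csv"
    if fmt == "csv":
        return read_csv(path)
    if fmt == "picasso-hdf5":
        return read_picasso_hdf5(path, pixel_nm)
    raise ValueError(f"unknown format {fmt!r}")


def write_particles_csv(particles, path, labels=None) -> Path:
    """Write a list of LocalizationSets to the package CSV schema."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, p in enumerate(particles):
        rec = {"particle_id": p.particle_id if p.particle_id is not None else k,
               "x_nm": p.coords[:, 0], "y_nm": p.coords[:, 1],
               "sigma_nm": p.sigma}
        if p.dim == 3:
            rec["z_nm"] = p.coords[:, 2]
            rec["sigma_z_nm"] = p.sigma_z if p.sigma_z is not None else p.sigma
        if labels is not None:
            rec["true_class"] = int(labels[k])
        rows.append(pd.DataFrame(rec))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    return path
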