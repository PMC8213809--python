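"""Synthetic SMLM particle datasets with ground-truth class labels.

Emulates the statistical structure of picked DNA-origami / nuclear-pore
particle data: designed binding-site templates observed under
underlabeling (density of labeling, DoL), several localizations per
bound site, Gaussian localization noise with a per-localization
uncertainty σ, random in-plane pose, optional mirroring of a
subpopulation, and optional elliptical deformation.

Raw-camera-frame effects (blinking kinetics, drift, PSF shape) are out
of scope; the generator produces localization tables directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .particles import LocalizationSet, RigidTransform

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_NM = 130.0


@dataclass
class SiteTemplate:
    """Designed binding-site geometry, centered at the origin (nm)."""

    site_coords: np.ndarray
    name: str = "template"
    symmetry_fold: Optional[int] = None

    def __post_init__(self) -> None:
        self.site_coords = np.atleast_2d(np.asarray(self.site_coords, float))
        if self.site_coords.shape[0] < 2:
            raise ValueError("a template needs at least 2 sites")
        if self.site_coords.shape[1] not in (2, 3):
            raise ValueError("sites must be 2D or 3D")
        if pdist(self.site_coords).min() <= 0:
            raise ValueError("duplicate site positions")
        self.site_coords = self.site_coords - self.site_coords.mean(axis=0)

    @property
    def n_sites(self) -> int:
        return self.site_coords.shape[0]

    @property
    def dim(self) -> int:
        return self.site_coords.shape[1]

    def extent(self) -> float:
        return float(pdist(self.site_coords).max())


# Letter/digit-like dot patterns on a unit lattice (column, row) — scaled
# by `spacing` in make_template.  Row 0 is the bottom of the glyph.
_DOT_PATTERNS = {
    "digit1": [(1, 0), (1, 1), (1, 2), (1, 3), (1, 4), (0, 3)],
    "digit2": [(0, 0), (1, 0), (2, 0), (0, 1), (1, 2), (2, 3), (0, 4), (1, 4), (2, 4)],
    "digit3": [(0, 0), (1, 0), (2, 1), (1, 2), (2, 3), (0, 4), (1, 4)],
    "L": [(0, 0), (1, 0), (2, 0), (0, 1), (0, 2), (0, 3), (0, 4)],
    "T": [(0, 4), (1, 4), (2, 4), (1, 3), (1, 2), (1, 1), (1, 0)],
    "O": [(0, 1), (0, 2), (0, 3), (1, 0), (1, 4), (2, 1), (2, 2), (2, 3)],
    # strongly chiral glyphs (low self-overlap with their mirror image
    # under any rotation) for mirrored-subpopulation studies
    "flag": [(0, 0), (0, 1), (0, 2), (0, 3), (0, 4), (1, 4), (2, 4), (1, 3)],
    # "logo" is deliberately off-lattice: every lattice glyph shares ~40%
    # of its sites with its own mirror image once the lattices align, so
    # genuinely chiral test structures need continuous site positions
    "logo": [(0.72, 0.20), (0.77, -1.77), (1.67, -1.98), (-0.49, 0.69),
             (-1.65, 1.80), (-1.64, -0.11), (-0.03, 1.48), (-0.01, -0.37),
             (1.28, 1.38), (-0.63, -1.33)],
    # 12-site patterns matching the 4x3 grid's site count: with equal
    # labeling statistics the similarity magnitudes of all classes are
    # comparable and only structure drives the dissimilarities
    "ladder": [(c, 0) for c in range(6)] + [(c, 1) for c in range(6)],
    "blob12": [(-1.58, -1.34), (2.00, 0.39), (-1.54, -0.36), (0.39, -1.73),
               (1.66, -1.96), (-0.05, 0.06), (1.68, 2.26), (1.47, -1.06),
               (-2.00, 2.34), (-0.52, -0.95), (0.35, 1.34), (-1.86, 1.01)],
}


def make_template(kind: str, **params) -> SiteTemplate:
    """Construct a named binding-site template.

    Kinds
    -----
    grid : rows=3, cols=4, spacing=20
        Rectangular lattice, e.g. the 12-site 4 × 3 origami grid with
        20 nm nearest-neighbor spacing.
    ring : n_fold=8, diameter=107
        ``n_fold`` sites equally spaced on a circle (NPC-like).
    dots : pattern="digit1" | explicit list, spacing=20
        Letter/digit-like dot patterns.
    tetrahedron : edge=100, height=90
        3D: equilateral base triangle of the given edge plus an apex at
        the given height above the base plane.
    """
    if kind == "grid":
        rows = int(params.get("rows", 3))
        cols = int(params.get("cols", 4))
        spacing = float(params.get("spacing", 20.0))
        if spacing <= 0:
            raise ValueError("spacing must be > 0")
        if rows < 1 or cols < 1 or rows * cols < 2:
            raise ValueError("grid too small")
        pts = [(c * spacing, r * spacing) for r in range(rows) for c in range(cols)]
        return SiteTemplate(np.array(pts), name=f"grid{cols}x{rows}")
    if kind == "ring":
        n_fold = int(params.get("n_fold", 8))
        diameter = float(params.get("diameter", 107.0))
        if diameter <= 0:
            raise ValueError("diameter must be > 0")
        if n_fold < 2:
            raise ValueError("a ring needs at least 2 sites")
        ang = 2 * np.pi * np.arange(n_fold) / n_fold
        pts = 0.5 * diameter * np.c_[np.cos(ang), np.sin(ang)]
        return SiteTemplate(pts, name=f"ring{n_fold}", symmetry_fold=n_fold)
    if kind == "dots":
        pattern = params.get("pattern", "digit1")
        spacing = float(params.get("spacing", 20.0))
        if spacing <= 0:
            raise ValueError("spacing must be > 0")
        if isinstance(pattern, str):
            if pattern not in _DOT_PATTERNS:
                raise ValueError(f"unknown dot pattern {pattern!r}; "
                                 f"available: {sorted(_DOT_PATTERNS)}")
            pts = np.asarray(_DOT_PATTERNS[pattern], float)
            name = f"dots-{pattern}"
        else:
            pts = np.asarray(pattern, float)
            name = "dots-custom"
        return SiteTemplate(pts * spacing, name=name)
    if kind == "tetrahedron":
        edge = float(params.get("edge", 100.0))
        height = float(params.get("height", 90.0))
        if edge <= 0 or height <= 0:
            raise ValueError("edge and height must be > 0")
        r = edge / np.sqrt(3.0)  # circumradius of the base triangle
        ang = 2 * np.pi * np.arange(3) / 3
        base = np.c_[r * np.cos(ang), r * np.sin(ang), np.zeros(3)]
        apex = np.array([[0.0, 0.0, height]])
        return SiteTemplate(np.vstack([base, apex]), name="tetrahedron")
    raise ValueError(f"unknown template kind {kind!r}")


@dataclass
class AcquisitionModel:
    """Image-formation statistics of the localization process.

    Parameters
    ----------
    dol : float
        Density of labeling — probability in (0, 1] that a binding site
        carries a functional label.
    locs_mean : float
        Mean localizations per labeled site; counts are Poisson unless
        ``locs_dist="fixed"``.
    sigma_mean : float
        Mean lateral localization uncertainty in nm; σ is Gamma
        distributed (shape ``sigma_shape``) unless ``sigma_dist="fixed"``.
    sigma_z_mean : float, optional
        Mean axial uncertainty for 3D templates (e.g. 8 nm); defaults to
        ``sigma_mean`` when omitted on 3D data.
    pixel_nm : float
        Effective camera pixel size in nm (default 130).
    """

    dol: float = 0.7
    locs_mean: float = 8.0
    locs_dist: str = "poisson"
    sigma_mean: float = 2.0
    sigma_shape: float = 9.0
    sigma_dist: str = "gamma"
    sigma_z_mean: Optional[float] = None
    pixel_nm: float = DEFAULT_PIXEL_NM

    def __post_init__(self) -> None:
        if not 0 < self.dol <= 1:
            raise ValueError("dol must be in (0, 1]")
        if self.locs_mean <= 0:
            raise ValueError("locs_mean must be > 0")
        if self.sigma_mean <= 0 or (self.sigma_z_mean is not None
                                    and self.sigma_z_mean <= 0):
            raise ValueError("uncertainties must be > 0")
        if self.locs_dist not in ("poisson", "fixed"):
            raise ValueError("locs_dist must be 'poisson' or 'fixed'")
        if self.sigma_dist not in ("gamma", "fixed"):
            raise ValueError("sigma_dist must be 'gamma' or 'fixed'")

    def draw_counts(self, n_sites: int, rng: np.random.Generator) -> np.ndarray:
        if self.locs_dist == "fixed":
            return np.full(n_sites, int(round(self.locs_mean)))
        return rng.poisson(self.locs_mean, size=n_sites)

    def draw_sigma(self, n: int, mean: float, rng: np.random.Generator) -> np.ndarray:
        if self.sigma_dist == "fixed":
            return np.full(n, mean)
        return rng.gamma(self.sigma_shape, mean / self.sigma_shape, size=n)


@dataclass
class MixtureComponent:
    template: SiteTemplate
    fraction: float
    mirror: bool = False
    deformation: float = 1.0  # major/minor axis ratio of in-plane scaling
    z_scale: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.deformation) or self.deformation <= 0:
            raise ValueError("deformation must be finite and > 0")
        if not np.isfinite(self.z_scale) or self.z_scale <= 0:
            raise ValueError("z_scale must be finite and > 0")


@dataclass
class MixtureSpec:
    """Recipe for a labelled mixture dataset.

    ``count_mode="multinomial"`` draws each particle's class label
    independently from the fractions (rare-class counts fluctuate around
    their expectation); ``"exact"`` fixes the class counts to the
    largest-remainder rounding of fraction × n_particles.
    """

    components: Sequence[MixtureComponent]
    n_particles: int
    seed: int
    count_mode: str = "multinomial"

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        total = sum(c.fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component fractions sum to {total}, not 1")
        if self.count_mode not in ("multinomial", "exact"):
            raise ValueError("count_mode must be 'multinomial' or 'exact'")
        dims = {c.template.dim for c in self.components}
        if len(dims) > 1:
            raise ValueError("all templates must share dimensionality")


def _deform(coords: np.ndarray, e: float, z_scale: float) -> np.ndarray:
    """Area-preserving elliptical deformation: √e along x, 1/√e along y."""
    out = coords.copy()
    out[:, 0] *= np.sqrt(e)
    out[:, 1] /= np.sqrt(e)
    if out.shape[1] == 3:
        out[:, 2] *= z_scale
    return out


def sample_particle(template: SiteTemplate, acq: AcquisitionModel,
                    rng: np.random.Generator,
                    pose: Optional[RigidTransform] = None,
                    mirror: bool = False, deformation: float = 1.0,
                    z_scale: float = 1.0) -> LocalizationSet:
    """Draw one particle: labeled sites → localizations → noise → pose.

    Each site is retained with probability ``dol`` and emits a count of
    localizations; each localization gets its own σ and isotropic
    Gaussian noise.  Noise is added in the template frame (statistically
    identical to camera-frame noise, since isotropic Gaussians are
    rotation invariant), so with the same seed a mirrored draw is the
    exact reflection of the unmirrored one.  Degenerate draws with no
    retained site (or no localizations) are re-drawn and logged.
    """
    dim = template.dim
    if pose is None:
        pose = RigidTransform.identity(dim)
    sites = _deform(template.site_coords, deformation, z_scale)
    for attempt in range(1000):
        keep = rng.random(template.n_sites) < acq.dol
        counts = acq.draw_counts(template.n_sites, rng)
        counts[~keep] = 0
        total = int(counts.sum())
        if keep.any() and total > 0:
            break
        logger.info("degenerate draw (no retained site/localization); redrawing")
    else:  # pragma: no cover - dol>0 makes this astronomically unlikely
        raise RuntimeError("failed to draw a non-empty particle")
    centers = np.repeat(sites, counts, axis=0)
    sigma = acq.draw_sigma(total, acq.sigma_mean, rng)
    noise = rng.normal(size=(total, dim))
    coords = centers.copy()
    coords[:, 0] += noise[:, 0] * sigma
    coords[:, 1] += noise[:, 1] * sigma
    sigma_z = None
    if dim == 3:
        sz_mean = acq.sigma_z_mean if acq.sigma_z_mean is not None else acq.sigma_mean
        sigma_z = acq.draw_sigma(total, sz_mean, rng)
        coords[:, 2] += noise[:, 2] * sigma_z
    if mirror:
        coords[:, -1] *= -1
    coords = pose.apply(coords)
    return LocalizationSet(coords, sigma, sigma_z)


def _draw_pose(template: SiteTemplate, rng: np.random.Generator,
               jitter_frac: float = 0.25) -> RigidTransform:
    """Uniform random rotation plus bounded translational jitter
    (picked particles are already roughly centered)."""
    half = jitter_frac * template.extent()
    if template.dim == 2:
        theta = rng.uniform(0.0, 2 * np.pi)
        t = rng.uniform(-half, half, size=2)
        return RigidTransform(theta, t)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-half, half, size=3)
    return RigidTransform(R, t)


def _exact_counts(fractions: np.ndarray, n: int) -> np.ndarray:
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


@dataclass
class ParticleDataset:
    particles: list[LocalizationSet]
    labels: np.ndarray
    spec: Optional[MixtureSpec] = None
    acq: Optional[AcquisitionModel] = None
    class_names: list[str] = field(default_factory=list)
    poses: list[RigidTransform] = field(default_factory=list)

    @property
    def n_particles(self) -> int:
        return len(self.particles)


def make_dataset(spec: MixtureSpec, acq: AcquisitionModel) -> ParticleDataset:
    """Generate a labelled particle mixture, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    fractions = np.array([c.fraction for c in spec.components])
    if spec.count_mode == "exact":
        counts = _exact_counts(fractions, spec.n_particles)
        labels = np.repeat(np.arange(len(fractions)), counts)
        rng.shuffle(labels)
    else:
        labels = rng.choice(len(fractions), size=spec.n_particles, p=fractions)
    particles = []
    poses = []
    for k, lab in enumerate(labels):
        comp = spec.components[lab]
        pose = _draw_pose(comp.template, rng)
        p = sample_particle(comp.template, acq, rng, pose=pose,
                            mirror=comp.mirror, deformation=comp.deformation,
                            z_scale=comp.z_scale)
        p.particle_id = k
        particles.append(p)
        poses.append(pose)
    names = [c.template.name + ("~mirror" if c.mirror else "")
             for c in spec.components]
    return ParticleDataset(particles=particles, labels=np.asarray(labels),
                           spec=spec, acq=acq, class_names=names, poses=poses)


def dataset_to_frame(ds: ParticleDataset) -> pd.DataFrame:
    rows = []
    for pid, (p, lab) in enumerate(zip(ds.particles, ds.labels)):
        rec = {"particle_id": pid, "x_nm": p.coords[:, 0],
               "y_nm": p.coords[:, 1], "sigma_nm": p.sigma,
               "true_class": int(lab)}
        if p.dim == 3:
            rec["z_nm"] = p.coords[:, 2]
            rec["sigma_z_nm"] = p.sigma_z if p.sigma_z is not None else p.sigma
        rows.append(pd.DataFrame(rec))
    return pd.concat(rows, ignore_index=True)


def write_dataset(ds: ParticleDataset, path, manifest: bool = True) -> Path:
    """Write the localization CSV plus a JSON manifest of the recipe."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = dataset_to_frame(ds)
    cols = ["particle_id", "x_nm", "y_nm"]
    if "z_nm" in df.columns:
        cols.append("z_nm")
    cols.append("sigma_nm")
    if "sigma_z_nm" in df.columns:
        cols.append("sigma_z_nm")
    cols.append("true_class")
    df[cols].to_csv(path, index=False, float_format="%.17g")
    if manifest and ds.spec is not None:
        man = {
            "seed": ds.spec.seed,
            "n_particles": ds.spec.n_particles,
            "count_mode": ds.spec.count_mode,
            "components": [
                {"template": c.template.name,
                 "sites": c.template.site_coords.tolist(),
                 "fraction": c.fraction, "mirror": c.mirror,
                 "deformation": c.deformation, "z_scale": c.z_scale}
                for c in ds.spec.components
            ],
            "acquisition": {
                "dol": ds.acq.dol, "locs_mean": ds.acq.locs_mean,
                "locs_dist": ds.acq.locs_dist,
                "sigma_mean": ds.acq.sigma_mean,
                "sigma_shape": ds.acq.sigma_shape,
                "sigma_dist": ds.acq.sigma_dist,
                "sigma_z_mean": ds.acq.sigma_z_mean,
                "pixel_nm": ds.acq.pixel_nm,
            } if ds.acq is not None else None,
        }
        path.with_suffix(".manifest.json").write_text(json.dumps(man, indent=2))
    return path
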