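"""Pairwise rigid registration and the all-to-all dissimilarity matrix.

Pipeline block 1.  Every particle is registered onto every other particle
by maximizing a Gaussian-mixture-model (GMM) overlap — a Gaussian of
uniform width (the *scale*) is placed on every localization and the
total overlap between the two mixtures is maximized over in-plane
rotation and translation from several angular starts.  The quality of
each candidate registration is then measured with the Bhattacharyya
similarity

    S(a, b) = 1/(Ka·Kb) Σ_i Σ_j 1/(σ²_{a,i}+σ²_{b,j})
              · exp(−½ |r_{a,i} − T r_{b,j}|² / (σ²_{a,i}+σ²_{b,j})),

which, unlike the search objective, uses the measured per-localization
uncertainties and is normalized both by the localization counts and by
the variance sums so that scores of different pairs are comparable.
Similarities are converted to dissimilarities by D(a,b) = max(S) − S(a,b).

Reflections are never searched: a mirrored subpopulation registers badly
against the unmirrored one and separates through the dissimilarities.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import h5py
import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from . import _kernels
from .particles import LocalizationSet, RigidTransform

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_NM = 130.0


@dataclass
class RegistrationConfig:
    """Settings of the pairwise registration.

    Parameters
    ----------
    scale_px : float, optional
        GMM kernel width in camera pixels.  ``None`` means "determine by
        :func:`scale_sweep` before use".
    pixel_nm : float
        Camera pixel size in nm (conversion for ``scale_px``).
    n_angle_inits : int
        Number of angular starts of the local optimizer, uniform in
        [0, 2π).  Default 6.
    n_axis_inits, n_inplane_inits : int
        3D only: orientations of the rotation axis (icosahedron
        vertices) times in-plane angles per axis.
    xatol, frtol, maxfev : float, float, int
        Nelder–Mead termination: simplex spread (radians / scaled
        translation units), relative objective spread, and maximum
        objective evaluations per start.
    """

    scale_px: Optional[float] = None
    pixel_nm: float = DEFAULT_PIXEL_NM
    n_angle_inits: int = 6
    n_axis_inits: int = 12
    n_inplane_inits: int = 4
    xatol: float = 5e-3
    frtol: float = 1e-6
    maxfev: int = 100

    def __post_init__(self) -> None:
        if self.scale_px is not None and self.scale_px <= 0:
            raise ValueError("scale must be > 0")
        if self.n_angle_inits < 1:
            raise ValueError("need at least one angular initialization")
        if self.pixel_nm <= 0:
            raise ValueError("pixel size must be > 0")

    @property
    def scale_nm(self) -> float:
        if self.scale_px is None:
            raise ValueError("scale not set; run scale_sweep first")
        return self.scale_px * self.pixel_nm

    def registration_key(self) -> str:
        """Hash of every setting that affects registration output."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _check_pair(a: LocalizationSet, b: LocalizationSet) -> None:
    if a.dim != b.dim:
        raise ValueError("particles have different dimensionality")


def bhattacharyya_score(a: LocalizationSet, b: LocalizationSet,
                        t: Optional[RigidTransform] = None) -> float:
    """Bhattacharyya similarity of two clouds under transform ``t`` on b.

    Vectorized, cutoff-free evaluation of the double sum; both
    normalizations (1/(Ka·Kb) and 1/(σa²+σb²)) included.  In 3D with
    anisotropic uncertainties the exponent is evaluated per axis and the
    prefactor uses the geometric mean of the per-axis variance sums,
    which reduces to the isotropic form when σ_z = σ.
    """
    _check_pair(a, b)
    if t is None:
        t = RigidTransform.identity(a.dim)
    bc = t.apply(b.coords)
    diff = a.coords[:, None, :] - bc[None, :, :]
    v_lat = a.sigma2[:, None] + b.sigma2[None, :]
    if a.dim == 2:
        q = (diff**2).sum(axis=2) / v_lat
        pref = 1.0 / v_lat
    else:
        v_z = a.sigma2_z[:, None] + b.sigma2_z[None, :]
        q = (diff[:, :, 0]**2 + diff[:, :, 1]**2) / v_lat + diff[:, :, 2]**2 / v_z
        pref = 1.0 / np.cbrt(v_lat**2 * v_z)
    return float(np.sum(pref * np.exp(-0.5 * q)) / (a.n * b.n))


def gmm_overlap(a: LocalizationSet, b: LocalizationSet, scale_nm: float,
                t: Optional[RigidTransform] = None) -> float:
    """Overlap of the two uniform-width Gaussian mixtures (the
    registration objective), averaged over localization pairs.

    Each localization carries a Gaussian of width ``scale_nm``; the
    overlap of one pair is the Gaussian product integral
    (4πs²)^(−dim/2) · exp(−d²/(4s²)).  Localization uncertainties are
    deliberately ignored here — they enter only the Bhattacharyya score.
    """
    if scale_nm <= 0:
        raise ValueError("scale must be > 0")
    _check_pair(a, b)
    if t is None:
        t = RigidTransform.identity(a.dim)
    bc = t.apply(b.coords)
    d2 = ((a.coords[:, None, :] - bc[None, :, :])**2).sum(axis=2)
    pref = (4.0 * np.pi * scale_nm**2) ** (-a.dim / 2.0)
    return float(pref * np.exp(-d2 / (4.0 * scale_nm**2)).sum() / (a.n * b.n))


def _pack(particles: Sequence[LocalizationSet]):
    X = np.concatenate([p.coords[:, 0] for p in particles])
    Y = np.concatenate([p.coords[:, 1] for p in particles])
    S2 = np.concatenate([p.sigma2 for p in particles])
    off = np.zeros(len(particles) + 1, dtype=np.int64)
    off[1:] = np.cumsum([p.n for p in particles])
    return X, Y, S2, off


def _register_pair_2d(a: LocalizationSet, b: LocalizationSet,
                      cfg: RegistrationConfig):
    nmax = max(a.n, b.n)
    buf = np.empty(nmax)
    vbuf = np.empty(nmax)
    th, tx, ty, s, g, nfev = _kernels.register_pair_2d(
        np.ascontiguousarray(a.coords[:, 0]), np.ascontiguousarray(a.coords[:, 1]),
        a.sigma2, np.ascontiguousarray(b.coords[:, 0]),
        np.ascontiguousarray(b.coords[:, 1]), b.sigma2,
        cfg.scale_nm, cfg.n_angle_inits, cfg.xatol, cfg.frtol, cfg.maxfev,
        buf, vbuf)
    return RigidTransform(float(th), np.array([tx, ty])), float(s), \
        {"gmm": float(g), "nfev": int(nfev)}


def _icosahedron_axes() -> np.ndarray:
    phi = (1 + np.sqrt(5)) / 2
    v = np.array([[0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
                  [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
                  [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1]],
                 dtype=float)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _initial_rotations_3d(cfg: RegistrationConfig) -> list[Rotation]:
    """Starting rotations: icosahedron-vertex axis orientations crossed
    with in-plane angles, generalizing the six 2D starting angles."""
    rots = []
    z = np.array([0.0, 0.0, 1.0])
    for v in _icosahedron_axes()[:cfg.n_axis_inits]:
        axis = np.cross(z, v)
        nrm = np.linalg.norm(axis)
        if nrm < 1e-12:
            align = Rotation.identity() if v[2] > 0 else Rotation.from_rotvec([np.pi, 0, 0])
        else:
            ang = np.arccos(np.clip(v[2], -1, 1))
            align = Rotation.from_rotvec(axis / nrm * ang)
        for k in range(cfg.n_inplane_inits):
            phi = 2 * np.pi * k / cfg.n_inplane_inits
            rots.append(align * Rotation.from_rotvec([0, 0, phi]))
    return rots


def _register_pair_3d(a: LocalizationSet, b: LocalizationSet,
                      cfg: RegistrationConfig):
    s2 = cfg.scale_nm**2
    ac, bc = a.coords, b.coords

    def neg_overlap(p):
        R = Rotation.from_rotvec(p[:3])
        moved = R.apply(bc) + p[3:]
        d2 = ((ac[:, None, :] - moved[None, :, :])**2).sum(axis=2)
        return -np.exp(-d2 / (4.0 * s2)).sum()

    best = None
    nfev = 0
    for R0 in _initial_rotations_3d(cfg):
        t0 = a.centroid() - R0.apply(b.centroid())
        x0 = np.concatenate([R0.as_rotvec(), t0])
        res = minimize(neg_overlap, x0, method="Nelder-Mead",
                       options={"maxfev": cfg.maxfev * 4, "xatol": cfg.xatol,
                                "fatol": cfg.frtol * max(1.0, abs(neg_overlap(x0)))})
        nfev += res.nfev
        t = RigidTransform(Rotation.from_rotvec(res.x[:3]).as_matrix(), res.x[3:])
        s = bhattacharyya_score(a, b, t)
        if best is None or s > best[1]:
            best = (t, s, -res.fun)
    return best[0], best[1], {"gmm": best[2], "nfev": nfev}


def register_pair(a: LocalizationSet, b: LocalizationSet,
                  cfg: RegistrationConfig):
    """Register particle ``b`` onto particle ``a``.

    Returns
    -------
    (RigidTransform, float, dict)
        Best transform (mapping b's coordinates into a's frame), its
        Bhattacharyya similarity, and optimizer diagnostics.
    """
    _check_pair(a, b)
    if a.n < 3 or b.n < 3:
        logger.warning("pair with <3 localizations: scoring at identity")
        t = RigidTransform.identity(a.dim)
        return t, bhattacharyya_score(a, b, t), {"degenerate": True}
    if a.dim == 2:
        return _register_pair_2d(a, b, cfg)
    return _register_pair_3d(a, b, cfg)


def scale_sweep(particles: Sequence[LocalizationSet],
                cfg: Optional[RegistrationConfig] = None,
                n_pairs: int = 10, n_scales: int = 50,
                scale_range: tuple[float, float] = (0.001, 0.5),
                seed: Optional[int] = None):
    """Determine the GMM scale by sweeping it over a linear grid.

    ``n_pairs`` random particle pairs are registered at each of
    ``n_scales`` scales linearly spaced over ``scale_range`` (camera
    pixels; the default 0.001–0.5 px spans 0.13–65 nm at 130 nm/px).
    The quality of each registration is recorded as its Bhattacharyya
    similarity: being scale-free, it peaks where the GMM kernel width
    actually produces good registrations, whereas the raw mixture
    overlap varies monotonically with the kernel width (too small a
    scale overfits single localizations, too large a scale blurs
    neighboring binding sites together, yet the overlap itself keeps
    growing with blur).  Each pair's curve is normalized to its own
    maximum and the curves are averaged; the returned scale is the
    argmax of the average curve.

    Returns
    -------
    (float, ndarray, ndarray)
        Optimal scale in camera pixels, the scale grid, the averaged
        normalized overlap curve.
    """
    if len(particles) < 2:
        raise ValueError("scale sweep needs at least 2 particles")
    cfg = cfg or RegistrationConfig()
    rng = np.random.default_rng(seed)
    N = len(particles)
    n_pairs = min(n_pairs, N * (N - 1) // 2)
    pairs = set()
    while len(pairs) < n_pairs:
        i, j = rng.integers(0, N, size=2)
        if i != j:
            pairs.add((min(i, j), max(i, j)))
    scales = np.linspace(scale_range[0], scale_range[1], n_scales)
    curves = np.empty((len(pairs), n_scales))
    for row, (i, j) in enumerate(sorted(pairs)):
        a, b = particles[i], particles[j]
        for k, s_px in enumerate(scales):
            c = RegistrationConfig(scale_px=float(s_px), pixel_nm=cfg.pixel_nm,
                                   n_angle_inits=cfg.n_angle_inits,
                                   xatol=cfg.xatol, frtol=cfg.frtol,
                                   maxfev=cfg.maxfev)
            _, s, _ = register_pair(a, b, c)
            curves[row, k] = s
    mx = curves.max(axis=1, keepdims=True)
    mx[mx == 0] = 1.0
    mean_curve = (curves / mx).mean(axis=0)
    best = float(scales[int(np.argmax(mean_curve))])
    logger.info("scale sweep: optimum %.4f px (%.2f nm)", best,
                best * cfg.pixel_nm)
    return best, scales, mean_curve


@dataclass
class RegistrationResult:
    """All-to-all registration output.

    ``S`` is the symmetric Bhattacharyya similarity matrix, ``D`` the
    dissimilarity matrix D = max(S) − S (diagonal fixed to 0), and
    ``tparams`` the per-pair transform parameters mapping particle b
    onto particle a for a < b ((θ, tx, ty) in 2D; rotation vector plus
    translation in 3D).
    """

    S: np.ndarray
    D: np.ndarray
    tparams: np.ndarray
    dim: int
    cfg: RegistrationConfig
    ids: list = field(default_factory=list)

    @property
    def n_particles(self) -> int:
        return self.S.shape[0]

    def transform(self, a: int, b: int) -> RigidTransform:
        """Transform mapping particle ``b`` into particle ``a``'s frame."""
        if a == b:
            return RigidTransform.identity(self.dim)
        i, j = (a, b) if a < b else (b, a)
        p = self.tparams[i, j]
        if self.dim == 2:
            t = RigidTransform(float(p[0]), p[1:3].copy())
        else:
            t = RigidTransform(Rotation.from_rotvec(p[:3]).as_matrix(),
                               p[3:6].copy())
        return t if a < b else t.inverse()

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("S", data=self.S, compression="gzip")
            f.create_dataset("D", data=self.D, compression="gzip")
            f.create_dataset("tparams", data=self.tparams, compression="gzip")
            f.attrs["dim"] = self.dim
            f.attrs["registration_key"] = self.cfg.registration_key()
            f.attrs["cfg_json"] = json.dumps(asdict(self.cfg))
            f.attrs["ids_json"] = json.dumps(list(self.ids))

    @classmethod
    def load(cls, path) -> "RegistrationResult":
        with h5py.File(path, "r") as f:
            cfg = RegistrationConfig(**json.loads(f.attrs["cfg_json"]))
            return cls(S=f["S"][...], D=f["D"][...], tparams=f["tparams"][...],
                       dim=int(f.attrs["dim"]), cfg=cfg,
                       ids=json.loads(f.attrs["ids_json"]))


def _dissimilarity_from_s(S: np.ndarray) -> np.ndarray:
    off = ~np.eye(S.shape[0], dtype=bool)
    smax = S[off].max()
    D = smax - S
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def all_to_all(particles: Sequence[LocalizationSet],
               cfg: RegistrationConfig,
               progress: bool = False) -> RegistrationResult:
    """Register all N(N−1)/2 unordered pairs and build S and D.

    The pair computations are mutually independent and deterministic, so
    the result does not depend on evaluation order.
    """
    N = len(particles)
    if N < 2:
        raise ValueError("need at least 2 particles")
    dim = particles[0].dim
    for p in particles:
        if p.dim != dim:
            raise ValueError("mixed 2D/3D particle collections not supported")
    _ = cfg.scale_nm  # fail early if the scale was never set
    ids = [p.particle_id if p.particle_id is not None else k
           for k, p in enumerate(particles)]
    if dim == 2:
        X, Y, S2, off = _pack(particles)
        S = np.zeros((N, N))
        T = np.zeros((N, N, 3))
        rows = np.arange(N)
        chunks = np.array_split(rows, 20) if progress else [rows]
        iterator = chunks
        if progress:
            from tqdm import tqdm
            iterator = tqdm(chunks, desc="all-to-all registration")
        for chunk in iterator:
            if len(chunk) == 0:
                continue
            _kernels.all_pairs_2d(X, Y, S2, off, cfg.scale_nm,
                                  cfg.n_angle_inits, cfg.xatol, cfg.frtol,
                                  cfg.maxfev, S, T,
                                  int(chunk[0]), int(chunk[-1]) + 1)
    else:
        S = np.zeros((N, N))
        T = np.zeros((N, N, 6))
        for a in range(N):
            for b in range(a + 1, N):
                t, s, _ = register_pair(particles[a], particles[b], cfg)
                S[a, b] = S[b, a] = s
                T[a, b, :3] = Rotation.from_matrix(t.matrix).as_rotvec()
                T[a, b, 3:] = t.translation
    np.fill_diagonal(S, 0.0)
    D = _dissimilarity_from_s(S)
    return RegistrationResult(S=S, D=D, tparams=T, dim=dim, cfg=cfg, ids=ids)
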