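"""Core containers: localization clouds and rigid transforms.

An SMLM *particle* is one picked instance of a repeated structure,
represented as a point cloud of localizations with per-localization
uncertainties (in nm).  Everything downstream (registration, embedding,
fusion) operates on these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.spatial.distance import pdist


@dataclass
class RigidTransform:
    """Proper rigid transform (rotation + translation), 2D or 3D.

    Parameters
    ----------
    rotation : float or (3, 3) ndarray
        In-plane angle in radians (2D) or a proper rotation matrix (3D).
        Reflections (determinant −1) are rejected: mirrored structures
        must separate through the dissimilarity metric, they are never
        reached by a transform.
    translation : array_like
        Translation vector in nm, length 2 or 3.
    """

    rotation: Union[float, np.ndarray]
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        if np.isscalar(self.rotation) or np.ndim(self.rotation) == 0:
            self.rotation = float(self.rotation)
            if self.translation.shape != (2,):
                raise ValueError("2D transform needs a length-2 translation")
        else:
            R = np.asarray(self.rotation, dtype=float)
            if R.shape != (3, 3):
                raise ValueError("3D rotation must be a 3x3 matrix")
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
                raise ValueError("rotation matrix is not orthogonal")
            if np.linalg.det(R) < 0:
                raise ValueError("reflections are not rigid transforms here")
            self.rotation = R
            if self.translation.shape != (3,):
                raise ValueError("3D transform needs a length-3 translation")
        if not np.all(np.isfinite(self.translation)):
            raise ValueError("translation must be finite")

    @property
    def dim(self) -> int:
        return 2 if isinstance(self.rotation, float) else 3

    @property
    def matrix(self) -> np.ndarray:
        """Rotation as a matrix regardless of dimensionality."""
        if isinstance(self.rotation, float):
            c, s = np.cos(self.rotation), np.sin(self.rotation)
            return np.array([[c, -s], [s, c]])
        return self.rotation

    @classmethod
    def identity(cls, dim: int = 2) -> "RigidTransform":
        if dim == 2:
            return cls(0.0, np.zeros(2))
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.matrix.T + self.translation

    def inverse(self) -> "RigidTransform":
        R = self.matrix
        t = -R.T @ self.translation
        if self.dim == 2:
            return RigidTransform(-self.rotation, t)
        return RigidTransform(R.T.copy(), t)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        if self.dim != other.dim:
            raise ValueError("dimensionality mismatch")
        t = self.matrix @ other.translation + self.translation
        if self.dim == 2:
            return RigidTransform(self.rotation + other.rotation, t)
        return RigidTransform(self.matrix @ other.matrix, t)


@dataclass
class LocalizationSet:
    """One particle's localization cloud.

    Parameters
    ----------
    coords : (n, 2) or (n, 3) ndarray
        Localization positions in nm.
    sigma : (n,) ndarray
        Per-localization lateral uncertainty in nm, strictly positive.
    sigma_z : (n,) ndarray, optional
        Axial uncertainty in nm for 3D data; defaults to ``sigma``
        (isotropic) when omitted.
    particle_id : int or str, optional
    """

    coords: np.ndarray
    sigma: np.ndarray
    sigma_z: Optional[np.ndarray] = None
    particle_id: Optional[Union[int, str]] = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float).ravel()
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must be (n, 2) or (n, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("a particle needs at least one localization")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.sigma.shape[0] != self.coords.shape[0]:
            raise ValueError("sigma length must match localization count")
        if not np.all(self.sigma > 0):
            raise ValueError("all localization uncertainties must be > 0")
        if self.sigma_z is not None:
            self.sigma_z = np.asarray(self.sigma_z, dtype=float).ravel()
            if self.sigma_z.shape[0] != self.n:
                raise ValueError("sigma_z length must match localization count")
            if not np.all(self.sigma_z > 0):
                raise ValueError("all axial uncertainties must be > 0")
            if self.dim != 3:
                raise ValueError("sigma_z only applies to 3D data")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    @property
    def sigma2(self) -> np.ndarray:
        return self.sigma**2

    @property
    def sigma2_z(self) -> np.ndarray:
        s = self.sigma if self.sigma_z is None else self.sigma_z
        return s**2

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def extent(self) -> float:
        """Largest pairwise localization distance (nm)."""
        if self.n == 1:
            return 0.0
        return float(pdist(self.coords).max())

    def transformed(self, t: RigidTransform) -> "LocalizationSet":
        if t.dim != self.dim:
            raise ValueError("transform dimensionality mismatch")
        return LocalizationSet(
            t.apply(self.coords), self.sigma.copy(),
            None if self.sigma_z is None else self.sigma_z.copy(),
            self.particle_id,
        )

    def mirrored(self) -> "LocalizationSet":
        """Reflected copy: y → −y in 2D, z → −z in 3D."""
        c = self.coords.copy()
        c[:, -1] *= -1
        return LocalizationSet(
            c, self.sigma.copy(),
            None if self.sigma_z is None else self.sigma_z.copy(),
            self.particle_id,
        )

    def subsampled(self, max_n: int, rng: np.random.Generator) -> "LocalizationSet":
        """Random subset of at most ``max_n`` localizations (for speed)."""
        if self.n <= max_n:
            return self
        idx = rng.choice(self.n, size=max_n, replace=False)
        idx.sort()
        return LocalizationSet(
            self.coords[idx], self.sigma[idx],
            None if self.sigma_z is None else self.sigma_z[idx],
            self.particle_id,
        )


def pool(sets: list[LocalizationSet], particle_id=None) -> LocalizationSet:
    """Concatenate several localization clouds into one."""
    if not sets:
        raise ValueError("nothing to pool")
    coords = np.concatenate([s.coords for s in sets])
    sigma = np.concatenate([s.sigma for s in sets])
    if any(s.sigma_z is not None for s in sets):
        sigma_z = np.concatenate([
            s.sigma_z if s.sigma_z is not None else s.sigma for s in sets
        ])
    else:
        sigma_z = None
    return LocalizationSet(coords, sigma, sigma_z, particle_id)
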