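"""Continuous shape variation of ring-like classes.

Two quantities characterize a classified set of nuclear-pore-like
rings: the *ellipticity* e = a/b of an ellipse fitted to the ring's
binding-site blobs, and the *order parameter* ⟨cos 2(θ − θ̄)⟩ of the
fitted major-axis orientations (1 = all ellipses aligned, 0 = random
orientations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.measure import EllipseModel
from sklearn.cluster import KMeans

from .particles import LocalizationSet


@dataclass
class EllipseFit:
    center: np.ndarray
    a: float            # semi-major axis, nm
    b: float            # semi-minor axis, nm
    theta: float        # major-axis orientation in [0, π)
    site_medians: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("expect a >= b > 0")

    @property
    def ellipticity(self) -> float:
        return self.a / self.b


def _angular_init(coords: np.ndarray, n_sites: int) -> np.ndarray:
    """K-means seeds equispaced on a circle around the centroid, so one
    blob is never split between two seeds under random seeding."""
    c = coords.mean(axis=0)
    r = np.linalg.norm(coords - c, axis=1).mean()
    ang = 2 * np.pi * np.arange(n_sites) / n_sites
    return c + r * np.c_[np.cos(ang), np.sin(ang)]


def fit_ellipse_to_ring(locs: LocalizationSet, n_sites: int = 8,
                        seed: Optional[int] = None) -> EllipseFit:
    """Fit an ellipse to the per-blob medians of a ring-shaped cloud.

    The localizations are grouped into ``n_sites`` blobs by k-means
    (seeded angularly, so the grouping is deterministic), the
    coordinate-wise median of each blob is taken — which makes the fit
    robust to the imbalanced localization count per site — and a direct
    least-squares ellipse is fitted to the medians.
    """
    if locs.dim != 2:
        raise ValueError("ellipse fitting expects 2D localizations")
    if locs.n < n_sites:
        raise ValueError(f"need at least {n_sites} localizations")
    km = KMeans(n_clusters=n_sites, init=_angular_init(locs.coords, n_sites),
                n_init=1).fit(locs.coords)
    medians = np.array([np.median(locs.coords[km.labels_ == k], axis=0)
                        for k in range(n_sites)])
    model = EllipseModel.from_estimate(medians)
    if not model:
        raise ValueError("degenerate blob medians; ellipse fit failed")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = model.theta
    if b > a:  # ensure the reported orientation is the major axis
        a, b = b, a
        theta += np.pi / 2
    if b <= 0:
        raise ValueError("degenerate ellipse fit")
    return EllipseFit(center=np.array([xc, yc]), a=float(a), b=float(b),
                      theta=float(np.mod(theta, np.pi)),
                      site_medians=medians)


def director(angles: Sequence[float]) -> float:
    """Mean orientation of axial (period-π) angles via the doubled-angle
    circular mean: θ̄ = ½·atan2(⟨sin 2θ⟩, ⟨cos 2θ⟩)."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("no angles")
    s = np.mean(np.sin(2 * angles))
    c = np.mean(np.cos(2 * angles))
    return float(np.mod(0.5 * np.arctan2(s, c), np.pi))


def order_parameter(angles: Sequence[float]) -> float:
    """⟨cos 2(θ − θ̄)⟩ over ellipse orientations.

    1 means complete alignment; 0 is the expectation for homogeneously
    random orientations.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("no angles")
    th_bar = director(angles)
    return float(np.mean(np.cos(2 * (angles - th_bar))))
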