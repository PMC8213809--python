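"""Eigen-image merging of K clusters into C < K final classes.

When hunting small subpopulations the embedding is deliberately
over-clustered (large K); the K per-cluster reconstructions are then
mutually aligned, rendered to normalized images, decomposed by PCA
("eigen images"), projected onto the first eigen image, and the
resulting one-dimensional weights are grouped into C classes by
average-linkage hierarchical clustering.

The decomposition uses the Gram-matrix trick: instead of the N_pix²
covariance XXᵀ, the K×K matrix XᵀX is decomposed and its eigenvectors
are lifted via u = X a, which gives the same eigen images at a tiny
fraction of the cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .particles import LocalizationSet, RigidTransform, pool
from .registration import RegistrationConfig, all_to_all

logger = logging.getLogger(__name__)


@dataclass
class EigenImageSet:
    images: np.ndarray            # (K, n_pix, n_pix) normalized inputs
    eigen_images: np.ndarray      # (K, n_pix, n_pix), descending variance
    singular_values: np.ndarray   # eigenvalues of the Gram matrix XᵀX
    weights: np.ndarray           # projections onto the first eigen image
    extent: Optional[tuple] = None
    merge_map: Optional[np.ndarray] = None   # K → C assignment

    @property
    def K(self) -> int:
        return self.images.shape[0]


def align_clusters(fusions: Sequence[LocalizationSet],
                   cfg: RegistrationConfig,
                   max_align_locs: int = 120,
                   seed: int = 0):
    """Mutually register the K cluster reconstructions and bring them to
    a common frame (no pooling).

    Registration between reconstructions runs on random subsets of at
    most ``max_align_locs`` localizations each (the double-sum objective
    is quadratic in cloud size); the resulting transforms are applied to
    the full reconstructions.  The reference frame is the largest
    reconstruction (most localizations, ties to the lowest index): the
    majority structure defines the frame, so minority clusters that
    cannot align to it (e.g. mirrored copies) end up visibly different
    in the shared rendering instead of dragging the frame toward
    themselves.  Returns (aligned clusters, transforms).
    """
    fusions = list(fusions)
    if len(fusions) == 1:
        return [fusions[0]], [RigidTransform.identity(fusions[0].dim)]
    rng = np.random.default_rng(seed)
    small = [f.subsampled(max_align_locs, rng) for f in fusions]
    # only K(K-1)/2 pairs: afford twice the angular starts and a larger
    # evaluation budget than the particle-level all-to-all — lattice-like
    # structures have competing rotational optima that 6 starts can miss
    acfg = RegistrationConfig(scale_px=cfg.scale_px, pixel_nm=cfg.pixel_nm,
                              n_angle_inits=max(12, cfg.n_angle_inits),
                              xatol=cfg.xatol, frtol=cfg.frtol,
                              maxfev=max(150, cfg.maxfev))
    pairwise = all_to_all(small, acfg)
    sizes = np.array([f.n for f in fusions])
    ref = int(np.flatnonzero(sizes == sizes.max()).min())
    transforms = [pairwise.transform(ref, k) for k in range(len(fusions))]
    aligned = [f.transformed(t) for f, t in zip(fusions, transforms)]
    return aligned, transforms


def shared_extent(clusters: Sequence[LocalizationSet],
                  pad: float = 0.1) -> tuple:
    """Common square field of view: bounding box of all aligned clusters
    padded by ``pad`` of its size."""
    allc = np.concatenate([c.coords[:, :2] for c in clusters])
    lo = allc.min(axis=0)
    hi = allc.max(axis=0)
    size = float(max(hi - lo))
    size = size if size > 0 else 1.0
    center = 0.5 * (lo + hi)
    half = 0.5 * size * (1.0 + pad)
    return (center[0] - half, center[0] + half,
            center[1] - half, center[1] + half)


def render_image(locs: LocalizationSet, n_pix: int = 400,
                 extent: Optional[tuple] = None,
                 blur_px: float = 0.0) -> np.ndarray:
    """Bin localizations into an n_pix × n_pix histogram and normalize
    it to zero mean and unit 2-norm.

    As a rule of thumb the resulting pixel should be about ¼ of the
    localization uncertainty.  ``blur_px`` optionally smooths the raw
    histogram with a Gaussian (in pixels) before normalization: with
    sparse renderings the zero-blur images only correlate where
    localizations hit the very same pixel, so a blur of about the
    localization uncertainty makes image correlations measure blob
    overlap instead of pixel coincidence.  3D clouds are projected
    laterally.
    """
    if locs.n == 0:
        raise ValueError("empty localization set")
    if extent is None:
        extent = shared_extent([locs])
    x0, x1, y0, y1 = extent
    H, _, _ = np.histogram2d(locs.coords[:, 0], locs.coords[:, 1],
                             bins=n_pix, range=[[x0, x1], [y0, y1]])
    if blur_px > 0:
        from scipy.ndimage import gaussian_filter
        H = gaussian_filter(H, blur_px)
    H = H - H.mean()
    nrm = np.linalg.norm(H)
    if nrm == 0:
        raise ValueError("image is constant; nothing to normalize")
    return H / nrm


def eigen_images(images: np.ndarray, extent: Optional[tuple] = None
                 ) -> EigenImageSet:
    """PCA of K normalized images via the K×K Gram matrix.

    The eigenvalues of XᵀX (squared singular values of the image stack
    X) are sorted descending, eigenvectors a are lifted to eigen images
    u = X a and re-normalized.  Each eigen image's sign is fixed so its
    projection onto the mean input image is non-negative (the SVD sign
    is otherwise arbitrary, which would make the weights irreproducible).
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[0] < 2:
        raise ValueError("need a stack of at least 2 images")
    K = images.shape[0]
    X = images.reshape(K, -1).T                       # (N_pix², K)
    G = X.T @ X
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    U = X @ vecs                                      # lift: u = X a
    mean_img = X.mean(axis=1)
    eigs = np.empty_like(U)
    for k in range(K):
        u = U[:, k]
        nrm = np.linalg.norm(u)
        u = u / nrm if nrm > 1e-12 else u
        if u @ mean_img < 0:
            u = -u
        eigs[:, k] = u
    weights = X.T @ eigs[:, 0]
    return EigenImageSet(images=images,
                         eigen_images=eigs.T.reshape(K, *images.shape[1:]),
                         singular_values=vals, weights=weights,
                         extent=extent)


def merge_map_from_weights(weights: np.ndarray, C: int) -> np.ndarray:
    """Average-linkage HAC of the 1D first-eigen-image weights, cut at C
    clusters; returns the K → C assignment (labels 0..C−1, relabelled in
    order of first appearance for determinism)."""
    K = len(weights)
    if not 1 <= C <= K:
        raise ValueError(f"C={C} outside [1, {K}]")
    if C == K:
        raw = np.arange(K)
    elif C == 1:
        raw = np.zeros(K, dtype=int)
    else:
        Z = linkage(np.asarray(weights, float)[:, None], method="average")
        raw = fcluster(Z, C, criterion="maxclust") - 1
    out = np.empty(K, dtype=int)
    seen: dict[int, int] = {}
    for k, r in enumerate(raw):
        if r not in seen:
            seen[r] = len(seen)
        out[k] = seen[r]
    return out


def project_and_merge(eis: EigenImageSet, C: int,
                      aligned_clusters: Optional[Sequence[LocalizationSet]] = None):
    """Cluster the first-eigen-image weights into C classes and fuse the
    co-assigned (already aligned) clusters.

    Returns (merge_map, merged classes) where the merged classes pool
    the aligned clusters' localizations per final class (or ``None``
    when no clusters were supplied).
    """
    merge_map = merge_map_from_weights(eis.weights, C)
    eis.merge_map = merge_map
    merged = None
    if aligned_clusters is not None:
        if len(aligned_clusters) != eis.K:
            raise ValueError("cluster count does not match image count")
        merged = []
        for c in range(merge_map.max() + 1):
            members = [aligned_clusters[k] for k in np.flatnonzero(merge_map == c)]
            cls = pool(members)
            cls.particle_id = f"class-{c}"
            merged.append(cls)
    return merge_map, merged
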