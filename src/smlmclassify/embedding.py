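"""Metric MDS embedding of the dissimilarity matrix and k-means
clustering of the embedded particles (pipeline blocks 2–3).

The dissimilarities are embedded by iterative stress majorization
(SMACOF) initialized from the classical (Torgerson) solution.  The
quality measure is the normalized metric stress

    Stress = sqrt( Σ_{i<j} (d_ij − ‖x_i − x_j‖)² / Σ_{i<j} d_ij² ),

which SMACOF decreases monotonically.  The default target
dimensionality is 30 — empirically anything above ~15 suffices for
multi-class particle data, and doubling that gives headroom.

K-means is restarted many times (default 1000; for rare-class hunting
use at least as many restarts as particles) and the restart with the
lowest within-cluster sum of point-to-centroid distances is kept.
Silhouette evaluation is computed on the first three embedding
dimensions, which carry the dominant variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

__all__ = ["Embedding", "ClusterResult", "stress", "mds_embed",
           "kmeans_cluster", "silhouette_values", "suggest_K"]


@dataclass
class Embedding:
    X: np.ndarray          # (N, d) coordinates
    stress: float          # achieved normalized stress
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_iter: int = 0

    @property
    def n_particles(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass
class ClusterResult:
    labels: np.ndarray
    K: int
    objective: float               # within-cluster sum of point-to-centroid distances
    restart_objectives: np.ndarray = field(default_factory=lambda: np.empty(0))
    silhouette: Optional[np.ndarray] = None
    mean_silhouette: Optional[float] = None

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("D must be symmetric")
    if (D < -1e-12).any():
        raise ValueError("D must be non-negative")
    return 0.5 * (D + D.T)


def stress(D: np.ndarray, X: np.ndarray) -> float:
    """Normalized metric stress of configuration ``X`` w.r.t. ``D``."""
    D = _check_dissimilarity(D)
    X = np.asarray(X, dtype=float)
    if X.shape[0] != D.shape[0]:
        raise ValueError("X and D size mismatch")
    dvec = squareform(D, checks=False)
    denom = float(np.sum(dvec**2))
    if denom == 0:
        raise ValueError("all-zero dissimilarity matrix")
    evec = pdist(X)
    return float(np.sqrt(np.sum((dvec - evec) ** 2) / denom))


def _classical_mds(D: np.ndarray, d: int) -> np.ndarray:
    N = D.shape[0]
    J = np.eye(N) - np.ones((N, N)) / N
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:d]
    lam = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(lam)


def mds_embed(D: np.ndarray, d: int = 30, seed: Optional[int] = None,
              tol: float = 1e-6, max_iter: int = 300,
              init: str = "classical") -> Embedding:
    """Embed a dissimilarity matrix by SMACOF stress majorization.

    The Guttman transform is iterated from the classical-MDS solution
    (or from a seeded random configuration with ``init="random"``) until
    the relative stress decrease falls below ``tol``.  The stress
    sequence is non-increasing by construction and is returned as the
    convergence trace.  ``d`` is capped at N − 1.
    """
    D = _check_dissimilarity(D)
    N = D.shape[0]
    if d < 1:
        raise ValueError("d must be >= 1")
    if d > N - 1:
        d = max(1, N - 1)
    if init == "classical":
        X = _classical_mds(D, d)
    elif init == "random":
        rng = np.random.default_rng(seed)
        scale = D.max() if D.max() > 0 else 1.0
        X = rng.normal(scale=scale / np.sqrt(d), size=(N, d))
    else:
        raise ValueError("init must be 'classical' or 'random'")
    denom = np.sum(squareform(D, checks=False) ** 2)
    if denom == 0:
        raise ValueError("all-zero dissimilarity matrix")
    trace = [stress(D, X)]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        E = squareform(pdist(X), checks=False)
        np.fill_diagonal(E, 1.0)
        E[E < 1e-12] = 1e-12
        ratio = D / E
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / N
        trace.append(stress(D, X))
        if trace[-2] - trace[-1] < tol * max(trace[-2], 1e-300):
            break
    return Embedding(X=X, stress=trace[-1], trace=np.asarray(trace),
                     n_iter=n_iter)


def _within_cluster_distance_sum(X: np.ndarray, labels: np.ndarray,
                                 K: int) -> float:
    obj = 0.0
    for k in range(K):
        pts = X[labels == k]
        if len(pts):
            c = pts.mean(axis=0)
            obj += float(np.sqrt(((pts - c) ** 2).sum(axis=1)).sum())
    return obj


def kmeans_cluster(X: np.ndarray, K: int, n_repeats: int = 1000,
                   seed: Optional[int] = None) -> ClusterResult:
    """Multi-restart k-means; keep the restart with the lowest
    within-cluster sum of point-to-centroid distances.

    Each restart seeds Lloyd's algorithm with K particles drawn
    uniformly at random.  Ties between restarts keep the first
    (seed-ordered) solution, so results are deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[0]
    if not 1 <= K <= N:
        raise ValueError(f"K={K} outside [1, {N}]")
    if K == N:
        labels = np.arange(N)
        return ClusterResult(labels=labels, K=K, objective=0.0,
                             restart_objectives=np.zeros(1))
    states = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    best_labels = None
    best_obj = np.inf
    objectives = np.empty(n_repeats)
    for r in range(n_repeats):
        km = KMeans(n_clusters=K, init="random", n_init=1,
                    random_state=int(states[r]), algorithm="lloyd").fit(X)
        obj = _within_cluster_distance_sum(X, km.labels_, K)
        objectives[r] = obj
        if obj < best_obj:
            best_obj = obj
            best_labels = km.labels_.copy()
    return ClusterResult(labels=best_labels, K=K, objective=best_obj,
                         restart_objectives=objectives)


def silhouette_values(X_first3: np.ndarray, labels: np.ndarray):
    """Per-particle silhouette values (b−a)/max(a, b) and their mean.

    Distances are Euclidean on the supplied coordinates — by convention
    the first three MDS dimensions.  Particles in singleton clusters get
    value 0.
    """
    X_first3 = np.asarray(X_first3, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    vals = silhouette_samples(X_first3, labels)
    return vals, float(vals.mean())


def suggest_K(D: np.ndarray, K_range: Sequence[int], d: int = 30,
              seed: Optional[int] = None, n_repeats: int = 200,
              embedding: Optional[Embedding] = None):
    """Mean silhouette (on the first 3 MDS dims) for each candidate K.

    Returns a list of (K, mean silhouette) pairs and the argmax K — a
    *suggestion* for visual confirmation, never a hard decision: flat
    profiles (single-class data) give an uninformative argmax.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("empty K range")
    emb = embedding if embedding is not None else mds_embed(D, d=d, seed=seed)
    ss = np.random.SeedSequence(seed).spawn(len(K_range))
    table = []
    for K, sub in zip(K_range, ss):
        res = kmeans_cluster(emb.X, K, n_repeats=n_repeats,
                             seed=sub.generate_state(1)[0] % (2**31))
        _, mean_sil = silhouette_values(emb.X[:, :3], res.labels)
        table.append((K, mean_sil))
    best_K = max(table, key=lambda kv: kv[1])[0]
    return table, best_K
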