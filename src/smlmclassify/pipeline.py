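"""End-to-end classification pipeline and its run-directory layout.

`classify_particles` is the in-memory core: all-to-all registration →
MDS embedding → multi-restart k-means → per-cluster fusion → optional
eigen-image merging to C final classes.  `run_pipeline` wraps it with
file I/O, the registration cache (the all-to-all step dominates cost
and is reused across re-runs with different K or C) and a JSON manifest
recording every seed and setting.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .embedding import Embedding, ClusterResult, kmeans_cluster, mds_embed, \
    silhouette_values, suggest_K
from .eigenmerge import align_clusters, eigen_images, project_and_merge, \
    render_image, shared_extent
from .fusion import FusedReconstruction, fuse_cluster, fuse_grid_structure
from .io import read_localizations, write_particles_csv
from .particles import LocalizationSet
from .registration import RegistrationConfig, RegistrationResult, all_to_all, \
    scale_sweep

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings of one classification run."""

    input_path: Optional[str] = None
    output_dir: Optional[str] = None
    pixel_nm: float = 130.0
    scale_px: Optional[float] = None       # None -> automatic scale sweep
    n_angle_inits: int = 6
    maxfev: int = 100
    embed_dims: int = 30
    K: Optional[int] = None                # None -> silhouette suggestion
    K_range: Sequence[int] = field(default_factory=lambda: range(2, 11))
    n_repeats: int = 1000
    merge_C: Optional[int] = None          # eigen-image merge target
    fusion_variant: str = "standard"       # or "grid"
    render_pix: int = 400
    render_blur_px: float = 2.0   # 0 disables the pre-blur (raw histograms)
    seed: int = 0

    def registration_config(self) -> RegistrationConfig:
        return RegistrationConfig(scale_px=self.scale_px,
                                  pixel_nm=self.pixel_nm,
                                  n_angle_inits=self.n_angle_inits,
                                  maxfev=self.maxfev)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class ClassificationResult:
    particles: list[LocalizationSet]
    registration: RegistrationResult
    embedding: Embedding
    clusters: ClusterResult
    fusions: list[FusedReconstruction]
    scale_px: float
    merge_map: Optional[np.ndarray] = None
    final_classes: Optional[list[LocalizationSet]] = None
    final_labels: Optional[np.ndarray] = None
    eigen: Optional[object] = None
    timings: dict = field(default_factory=dict)

    @property
    def cluster_labels(self) -> np.ndarray:
        return self.clusters.labels

    def labels(self) -> np.ndarray:
        """Final per-particle class labels (after merging if enabled)."""
        return self.final_labels if self.final_labels is not None \
            else self.clusters.labels


def classify_particles(particles: Sequence[LocalizationSet],
                       cfg: PipelineConfig,
                       pairwise: Optional[RegistrationResult] = None,
                       progress: bool = False) -> ClassificationResult:
    """Run the full pipeline on in-memory particles.

    A precomputed `RegistrationResult` (e.g. from a cache) skips the
    expensive all-to-all step; its settings must match the config.
    """
    particles = list(particles)
    timings: dict[str, float] = {}
    rcfg = cfg.registration_config()
    if pairwise is None:
        if rcfg.scale_px is None:
            t0 = time.perf_counter()
            best, _, _ = scale_sweep(particles, rcfg, seed=cfg.seed)
            rcfg.scale_px = best
            timings["scale_sweep"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        pairwise = all_to_all(particles, rcfg, progress=progress)
        timings["all_to_all"] = time.perf_counter() - t0
    else:
        logger.info("reusing precomputed all-to-all registration")
    t0 = time.perf_counter()
    emb = mds_embed(pairwise.D, d=cfg.embed_dims, seed=cfg.seed)
    timings["mds"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    if cfg.K is None:
        table, K = suggest_K(pairwise.D, cfg.K_range, d=cfg.embed_dims,
                             seed=cfg.seed, embedding=emb)
        logger.info("silhouette K suggestion: %s -> K=%d", table, K)
    else:
        K = cfg.K
    clusters = kmeans_cluster(emb.X, K, n_repeats=cfg.n_repeats, seed=cfg.seed)
    if K >= 2:
        sil, mean_sil = silhouette_values(emb.X[:, :3], clusters.labels)
        clusters.silhouette = sil
        clusters.mean_silhouette = mean_sil
    timings["kmeans"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    fcfg = RegistrationConfig(scale_px=pairwise.cfg.scale_px,
                              pixel_nm=cfg.pixel_nm,
                              n_angle_inits=cfg.n_angle_inits,
                              maxfev=cfg.maxfev)
    fusions = []
    for k in range(K):
        members = np.flatnonzero(clusters.labels == k)
        if cfg.fusion_variant == "grid":
            fusions.append(fuse_grid_structure(particles, members, fcfg))
        else:
            fusions.append(fuse_cluster(particles, members, pairwise))
    timings["fusion"] = time.perf_counter() - t0
    merge_map = None
    final_classes = None
    final_labels = None
    eigen = None
    if cfg.merge_C is not None and K > 1:
        t0 = time.perf_counter()
        C = min(cfg.merge_C, K)
        aligned, _ = align_clusters([f.localizations for f in fusions],
                                    fcfg, seed=cfg.seed)
        ext = shared_extent(aligned)
        imgs = np.stack([render_image(a, n_pix=cfg.render_pix, extent=ext,
                                      blur_px=cfg.render_blur_px)
                         for a in aligned])
        eigen = eigen_images(imgs, extent=ext)
        merge_map, final_classes = project_and_merge(eigen, C, aligned)
        final_labels = merge_map[clusters.labels]
        timings["eigenmerge"] = time.perf_counter() - t0
    return ClassificationResult(particles=particles, registration=pairwise,
                                embedding=emb, clusters=clusters,
                                fusions=fusions, scale_px=rcfg.scale_px
                                if rcfg.scale_px is not None
                                else pairwise.cfg.scale_px,
                                merge_map=merge_map,
                                final_classes=final_classes,
                                final_labels=final_labels, eigen=eigen,
                                timings=timings)


def _cache_path(out_dir: Path) -> Path:
    return out_dir / "registration_cache.h5"


def load_cached_registration(out_dir, rcfg: RegistrationConfig
                             ) -> Optional[RegistrationResult]:
    """Return the cached all-to-all result if its registration-affecting
    settings match ``rcfg`` (changing only K or C keeps the cache)."""
    path = _cache_path(Path(out_dir))
    if not path.exists():
        return None
    try:
        cached = RegistrationResult.load(path)
    except Exception:
        logger.warning("unreadable registration cache at %s", path)
        return None
    if cached.cfg.registration_key() != rcfg.registration_key():
        logger.info("registration settings changed; cache invalidated")
        return None
    return cached


def run_pipeline(cfg: PipelineConfig,
                 particles: Optional[Sequence[LocalizationSet]] = None,
                 truth: Optional[np.ndarray] = None,
                 progress: bool = False) -> ClassificationResult:
    """File-level pipeline: load, classify, persist intermediates."""
    if particles is None:
        if cfg.input_path is None:
            raise ValueError("either particles or input_path required")
        particles, truth = read_localizations(cfg.input_path,
                                              pixel_nm=cfg.pixel_nm)
    particles = list(particles)
    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    pairwise = None
    rcfg = cfg.registration_config()
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        if cfg.scale_px is None:
            sweep_seed = cfg.seed
            best, _, _ = scale_sweep(particles, rcfg, seed=sweep_seed)
            cfg.scale_px = best
            rcfg.scale_px = best
        pairwise = load_cached_registration(out_dir, rcfg)
    result = classify_particles(particles, cfg, pairwise=pairwise,
                                progress=progress)
    if out_dir is None:
        return result
    result.registration.save(_cache_path(out_dir))
    np.savetxt(out_dir / "embedding.csv", result.embedding.X, delimiter=",")
    labels_df = pd.DataFrame({
        "particle_id": [p.particle_id if p.particle_id is not None else i
                        for i, p in enumerate(particles)],
        "cluster_id": result.clusters.labels,
    })
    if result.final_labels is not None:
        labels_df["class_id"] = result.final_labels
    if result.clusters.silhouette is not None:
        labels_df["silhouette"] = result.clusters.silhouette
    if truth is not None:
        labels_df["true_class"] = truth
    labels_df.to_csv(out_dir / "labels.csv", index=False)
    classes = result.final_classes if result.final_classes is not None \
        else [f.localizations for f in result.fusions]
    cls_dir = out_dir / "classes"
    for k, cls in enumerate(classes):
        write_particles_csv([cls], cls_dir / f"class_{k}.csv")
    _render_reports(classes, out_dir)
    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, range) else v)
                   for k, v in asdict(cfg).items()},
        "n_particles": len(particles),
        "scale_px": result.scale_px,
        "stress": result.embedding.stress,
        "K": result.clusters.K,
        "mean_silhouette": result.clusters.mean_silhouette,
        "timings_s": result.timings,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def _render_reports(classes, out_dir: Path, n_pix: int = 256) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    ext = shared_extent(classes)
    for k, cls in enumerate(classes):
        img = render_image(cls, n_pix=n_pix, extent=ext)
        fig, axis = plt.subplots(figsize=(4, 4))
        axis.imshow(img.T, origin="lower", cmap="hot",
                    extent=[ext[0], ext[1], ext[2], ext[3]])
        axis.set_xlabel("x (nm)")
        axis.set_ylabel("y (nm)")
        axis.set_title(f"class {k}: {cls.n} localizations")
        fig.tight_layout()
        fig.savefig(out_dir / f"class_{k}.png", dpi=120)
        plt.close(fig)


def classification_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of correctly classified particles under the best
    one-to-one matching of predicted to true classes (Hungarian)."""
    from scipy.optimize import linear_sum_assignment
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("label vectors differ in length")
    np_, nt = pred.max() + 1, truth.max() + 1
    n = max(np_, nt)
    conf = np.zeros((n, n), dtype=int)
    for p, t in zip(pred, truth):
        conf[p, t] += 1
    rows, cols = linear_sum_assignment(-conf)
    return conf[rows, cols].sum() / len(pred)
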