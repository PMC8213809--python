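"""Per-cluster particle fusion (pipeline block 4).

Fusing pools the localizations of all cluster members in one common
frame, boosting the effective labeling density of the reconstruction.
The member with the highest mean similarity to all other members is the
reference frame; every other member is mapped in using the transform
already found during the all-to-all registration, so fusion adds almost
no cost.  An optional refinement pass re-registers each member against
the pooled cloud of the others.

For regular multi-site structures (e.g. the 12-site 20 nm grid) the raw
clouds are first condensed to binding-site centers with DBSCAN so an
unbalanced localization count per site cannot bias the registration;
after fusing the centers, the original localizations are restored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .particles import LocalizationSet, RigidTransform, pool
from .registration import (RegistrationConfig, RegistrationResult,
                           bhattacharyya_score, register_pair, all_to_all)

logger = logging.getLogger(__name__)


@dataclass
class FusedReconstruction:
    """Pooled localizations of one cluster in the reference frame."""

    localizations: LocalizationSet
    member_ids: list[int]
    transforms: list[RigidTransform]   # applied per member, same order
    reference: int
    n_noise_localizations: int = 0     # DBSCAN-noise bookkeeping (grid variant)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def _select_reference(member_ids: Sequence[int], S: np.ndarray) -> int:
    """Member with maximal mean similarity to the other members;
    ties break to the lowest particle id for determinism."""
    ids = np.asarray(member_ids)
    if len(ids) == 1:
        return int(ids[0])
    sub = S[np.ix_(ids, ids)]
    mean_s = (sub.sum(axis=1)) / (len(ids) - 1)
    best = np.flatnonzero(mean_s == mean_s.max())
    return int(ids[best].min())


def fuse_cluster(particles: Sequence[LocalizationSet],
                 member_ids: Sequence[int],
                 pairwise: RegistrationResult,
                 refine: bool = False,
                 cfg: Optional[RegistrationConfig] = None,
                 max_refine_locs: int = 600,
                 seed: int = 0) -> FusedReconstruction:
    """Fuse cluster members into the best-connected member's frame."""
    member_ids = [int(m) for m in member_ids]
    if not member_ids:
        raise ValueError("empty cluster")
    ref = _select_reference(member_ids, pairwise.S)
    transforms = [pairwise.transform(ref, m) for m in member_ids]
    moved = [particles[m].transformed(t) for m, t in zip(member_ids, transforms)]
    if refine and len(member_ids) > 1:
        cfg = cfg or pairwise.cfg
        rng = np.random.default_rng(seed)
        refined = []
        for k, m in enumerate(member_ids):
            others = [mv for i, mv in enumerate(moved) if i != k]
            target = pool(others).subsampled(max_refine_locs, rng)
            t, s, _ = register_pair(target, moved[k], cfg)
            s0 = bhattacharyya_score(target, moved[k])
            if s >= s0:
                refined.append((moved[k].transformed(t),
                                t.compose(transforms[k])))
            else:
                refined.append((moved[k], transforms[k]))
        moved = [r[0] for r in refined]
        transforms = [r[1] for r in refined]
    fused = pool(moved)
    fused.particle_id = f"cluster-ref{ref}"
    return FusedReconstruction(localizations=fused, member_ids=member_ids,
                               transforms=transforms, reference=ref)


def detect_sites(p: LocalizationSet, eps_px: float = 0.03, min_pts: int = 4,
                 pixel_nm: float = 130.0):
    """Group one particle's localizations into binding sites with DBSCAN.

    ``eps_px`` is in camera pixels (Euclidean, honoring the printed
    parameters); coordinates are converted from nm at the boundary.
    Returns (site centers LocalizationSet or None, per-localization site
    index with −1 for noise).
    """
    db = DBSCAN(eps=eps_px, min_samples=min_pts).fit(p.coords / pixel_nm)
    labs = db.labels_
    n_sites = labs.max() + 1
    if n_sites == 0:
        return None, labs
    centers = np.empty((n_sites, p.dim))
    sig = np.empty(n_sites)
    sig_z = np.empty(n_sites) if p.dim == 3 else None
    for k in range(n_sites):
        sel = labs == k
        centers[k] = p.coords[sel].mean(axis=0)
        sig[k] = p.sigma[sel].mean()  # mean member uncertainty per center
        if sig_z is not None:
            sz = p.sigma_z if p.sigma_z is not None else p.sigma
            sig_z[k] = sz[sel].mean()
    return LocalizationSet(centers, sig, sig_z, p.particle_id), labs


def fuse_grid_structure(particles: Sequence[LocalizationSet],
                        member_ids: Sequence[int],
                        cfg: RegistrationConfig,
                        eps_px: float = 0.03, min_pts: int = 4,
                        pairwise: Optional[RegistrationResult] = None
                        ) -> FusedReconstruction:
    """DBSCAN-variant fusion for regular multi-site structures.

    Each member is condensed to its detected site centers (carrying the
    mean localization uncertainty of the site) and the centers are
    registered all-to-all and fused; the final reconstruction replaces
    the centers by all original localizations, so no localization is
    dropped.  Members in which DBSCAN finds no site are kept as raw
    clouds, with a warning.
    """
    member_ids = [int(m) for m in member_ids]
    if not member_ids:
        raise ValueError("empty cluster")
    reduced = []
    n_noise = 0
    for m in member_ids:
        centers, labs = detect_sites(particles[m], eps_px, min_pts, cfg.pixel_nm)
        n_noise += int((labs == -1).sum())
        if centers is None:
            logger.warning("particle %s: DBSCAN found no site; using raw cloud", m)
            centers = particles[m]
        reduced.append(centers)
    if len(member_ids) == 1:
        rec = FusedReconstruction(localizations=particles[member_ids[0]],
                                  member_ids=member_ids,
                                  transforms=[RigidTransform.identity(particles[member_ids[0]].dim)],
                                  reference=member_ids[0],
                                  n_noise_localizations=n_noise)
        return rec
    centers_pairwise = all_to_all(reduced, cfg)
    local_ids = list(range(len(member_ids)))
    ref_local = _select_reference(local_ids, centers_pairwise.S)
    transforms = [centers_pairwise.transform(ref_local, i) for i in local_ids]
    moved = [particles[m].transformed(t)
             for m, t in zip(member_ids, transforms)]
    fused = pool(moved)
    fused.particle_id = f"cluster-ref{member_ids[ref_local]}"
    return FusedReconstruction(localizations=fused, member_ids=member_ids,
                               transforms=transforms,
                               reference=member_ids[ref_local],
                               n_noise_localizations=n_noise)
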