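"""Desk-scale simulation experiments used for validation.

These reproduce, on synthetic data, the two study designs that probe the
pipeline's limits: isolating a rare 9-fold-symmetric subpopulation
within 8-fold NPC-like rings (high-K clustering followed by eigen-image
merging to two classes), and the dependence of multi-class accuracy on
the MDS embedding dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .embedding import kmeans_cluster, mds_embed
from .pipeline import PipelineConfig, classification_accuracy, classify_particles
from .simdata import (AcquisitionModel, MixtureComponent, MixtureSpec,
                      make_dataset, make_template)

# Simulation conditions of the rare-class study: NPC-like rings of
# 107 nm diameter, 70% labeling, ~6 localizations per labeled site and
# ~3 nm localization uncertainty (clouds of ~35 localizations).
RARE_ACQ = AcquisitionModel(dol=0.7, locs_mean=6.0, sigma_mean=3.0)
RING_DIAMETER_NM = 107.0


def npc_mixture(n_particles: int, n_rare: int, seed: int,
                diameter: float = RING_DIAMETER_NM):
    """8-fold rings with ``n_rare`` 9-fold rings on the same diameter."""
    ring8 = make_template("ring", n_fold=8, diameter=diameter)
    ring9 = make_template("ring", n_fold=9, diameter=diameter)
    frac = n_rare / n_particles
    spec = MixtureSpec(
        components=[MixtureComponent(ring8, 1 - frac),
                    MixtureComponent(ring9, frac)],
        n_particles=n_particles, seed=seed, count_mode="exact")
    return make_dataset(spec, RARE_ACQ)


@dataclass
class RareClassOutcome:
    seed: int
    n_rare_true: int
    recall: float
    minority_size: int
    detected: bool
    class_sizes: tuple = ()


def rare_class_trial(n_particles: int, n_rare: int, seed: int,
                     K: int = 40, merge_C: int = 2,
                     n_repeats: Optional[int] = None,
                     maxfev: int = 100) -> RareClassOutcome:
    """One rare-class detection run.

    The mixture is over-clustered with a large K (the value used for
    rare-class hunting on the mirrored-logo data) and merged back to two
    classes via the eigen-image weights.  Detection succeeds when the
    minority output class captures at least 80% of the true 9-fold
    particles.
    """
    ds = npc_mixture(n_particles, n_rare, seed)
    cfg = PipelineConfig(K=K, merge_C=merge_C, maxfev=maxfev,
                         n_repeats=n_repeats if n_repeats is not None
                         else max(1000, n_particles),
                         seed=seed)
    res = classify_particles(ds.particles, cfg)
    labels = res.labels()
    truth = ds.labels
    rare_mask = truth == 1
    sizes = np.bincount(labels, minlength=2)
    minority = int(np.argmin(sizes))
    recall = float((labels[rare_mask] == minority).mean()) if rare_mask.any() else 0.0
    detected = recall >= 0.8 and sizes[minority] < len(labels) / 2
    return RareClassOutcome(seed=seed, n_rare_true=int(rare_mask.sum()),
                            recall=recall, minority_size=int(sizes[minority]),
                            detected=detected, class_sizes=tuple(sizes))


def rare_class_success(n_particles: int, n_rare: int, seeds: Sequence[int],
                       min_successes: int = 4, **kwargs):
    """Run the trial over several seeds; detection of the condition
    succeeds when at least ``min_successes`` seeds detect the rare class."""
    outcomes = [rare_class_trial(n_particles, n_rare, s, **kwargs)
                for s in seeds]
    n_ok = sum(o.detected for o in outcomes)
    return n_ok >= min_successes, outcomes


def four_class_mixture(n_particles: int = 200, seed: int = 0,
                       dol: float = 0.7):
    """The 12-site grid plus three structurally distinct 12-site dot
    templates (a 12-fold ring, a 2 × 6 ladder, an irregular off-lattice
    arrangement), equal fractions.

    All four templates carry the same number of binding sites: the
    similarity metric's magnitude scales inversely with the site count,
    so matching the counts makes the class magnitudes comparable and the
    dissimilarities purely structural.  Glyphs that are subsets of one
    lattice (e.g. two dot-matrix numerals) share most of their sites
    under underlabeling and make poor test classes.
    """
    templates = [make_template("grid", rows=3, cols=4, spacing=20.0),
                 make_template("ring", n_fold=12, diameter=80.0),
                 make_template("dots", pattern="ladder"),
                 make_template("dots", pattern="blob12")]
    acq = AcquisitionModel(dol=dol, locs_mean=8.0, sigma_mean=2.0)
    spec = MixtureSpec(
        components=[MixtureComponent(t, 0.25) for t in templates],
        n_particles=n_particles, seed=seed, count_mode="exact")
    return make_dataset(spec, acq)


@dataclass
class DimensionSweep:
    dims: list[int]
    accuracies: list[float]
    plateau_dim: int = 0
    plateau_accuracy: float = 0.0


def dimension_sweep(ds, D: np.ndarray, dims: Sequence[int] = (2, 5, 10, 15, 20, 30),
                    K: int = 4, n_repeats: int = 1000, seed: int = 0,
                    tolerance_pp: float = 1.0) -> DimensionSweep:
    """Classification accuracy versus MDS dimensionality.

    The dissimilarity matrix is embedded at each dimensionality and
    clustered with k-means (K classes, best of ``n_repeats`` restarts);
    accuracy is the ground-truth agreement under optimal class matching.
    The plateau is referenced to the largest dimensionality: the
    reported plateau onset is the smallest d whose accuracy is within
    ``tolerance_pp`` percentage points of it.
    """
    dims = sorted(dims)
    accs = []
    for d in dims:
        emb = mds_embed(D, d=d, seed=seed)
        res = kmeans_cluster(emb.X, K, n_repeats=n_repeats, seed=seed)
        accs.append(classification_accuracy(res.labels, ds.labels))
    ref = accs[-1]
    plateau_dim = dims[-1]
    for d, a in zip(dims, accs):
        if a >= ref - tolerance_pp / 100.0:
            plateau_dim = d
            break
    return DimensionSweep(dims=list(dims), accuracies=accs,
                          plateau_dim=plateau_dim, plateau_accuracy=ref)
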