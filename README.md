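# smlmclassify

Prior-knowledge-free classification of structurally heterogeneous
particles in single-molecule localization microscopy (SMLM) data.

SMLM of repeated structures (DNA-origami nanostructures, nuclear pore
complexes) yields many *particles*: picked point clouds of localization
coordinates with per-localization uncertainties. Fusing all particles
into one reconstruction assumes they are identical; real data mixes
designed classes, mirrored (upside-down) copies, rare symmetry variants
and continuous deformations. `smlmclassify` sorts the particles into
structural classes without templates or prior knowledge of the class
count, then fuses per class. It is aimed at microscopists and method
developers working with localization tables (CSV or Picasso-style HDF5).

## Method

For particles *a*, *b* with localizations `r` and uncertainties `σ`,
every unordered pair is rigidly registered (rotation + translation,
never reflection) by maximizing a Gaussian-mixture overlap with uniform
kernel width (the *scale*, chosen by an automatic sweep over 0.001–0.5
camera pixels), from six angular starts. Each candidate registration T
is scored with the Bhattacharyya similarity

```
S(a,b) = 1/(K_a K_b) · Σ_i Σ_j exp(−½ ‖r_a,i − T r_b,j‖² / (σ²_a,i + σ²_b,j)) / (σ²_a,i + σ²_b,j)
```

whose normalizations make scores comparable across pairs regardless of
localization count and uncertainty. Dissimilarities D(a,b) = max S −
S(a,b) are embedded into d = 30 dimensions by SMACOF metric MDS
(minimizing the normalized stress √(Σ(d_ij − ‖x_i−x_j‖)²/Σd_ij²)),
clustered by k-means (best of 1000 restarts by the within-cluster sum
of point-to-centroid distances, silhouette values guiding the choice of
K), and each cluster is fused into one reconstruction. To isolate rare
subpopulations the embedding is deliberately over-clustered (large K)
and the K aligned, rendered, normalized cluster images are reduced by
PCA ("eigen images", computed through the K×K Gram matrix); the
projections onto the first eigen image are grouped by average-linkage
hierarchical clustering into the final C classes. Ellipse fits to ring
blobs (e = a/b) and the orientation order parameter ⟨cos 2(θ−θ̄)⟩
quantify continuous shape variation.

A fully seeded synthetic-data generator (`smlmclassify.simdata`)
produces labelled mixtures of grids, N-fold rings, letter/digit dot
patterns and 3D tetrahedra under underlabeling, Poisson localization
counts, Gamma-distributed uncertainties, random pose, mirroring and
elliptical deformation — every stage of the pipeline is testable at
desk scale.

## Worked example

Simulate 8-fold NPC-like rings with a 2% 9-fold subpopulation, classify
with a large K, and merge back to two classes:

```python
import numpy as np
from smlmclassify import (AcquisitionModel, MixtureComponent, MixtureSpec,
                          PipelineConfig, classify_particles, make_dataset,
                          make_template)

ring8 = make_template("ring", n_fold=8, diameter=107.0)
ring9 = make_template("ring", n_fold=9, diameter=107.0)
spec = MixtureSpec(components=[MixtureComponent(ring8, 0.98),
                               MixtureComponent(ring9, 0.02)],
                   n_particles=500, seed=1, count_mode="exact")
acq = AcquisitionModel(dol=0.7, locs_mean=6.0, sigma_mean=3.0)
ds = make_dataset(spec, acq)

cfg = PipelineConfig(K=40, merge_C=2, n_repeats=1000, seed=1)
res = classify_particles(ds.particles, cfg)

labels = res.labels()
sizes = np.bincount(labels)
rare = ds.labels == 1
minority = int(np.argmin(sizes))
print("scale:", round(res.scale_px, 4), "px")
print("class sizes:", sizes.tolist())
print("9-fold recall:", (labels[rare] == minority).mean())
```

Output (about two minutes on one CPU):

```
scale: 0.0825 px
class sizes: [490, 10]
9-fold recall: 1.0
```

The sweep picks a 0.0825 px ≈ 10.7 nm kernel; the minority class
contains exactly the 10 true 9-fold rings. The same pipeline is
available from the shell:

```
smlmclassify simulate --template ring:n_fold=8 --template ring:n_fold=9 \
    --fractions 0.98,0.02 --n-particles 500 --dol 0.7 --locs-mean 6 \
    --sigma-mean 3 --seed 1 --out data/rings.csv
smlmclassify classify --input data/rings.csv --out runs/rings --k 40 --seed 1
smlmclassify merge --run-dir runs/rings --c 2
```

Each run directory keeps the registration cache (the expensive
all-to-all step), so re-running with a different K or C is fast.

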