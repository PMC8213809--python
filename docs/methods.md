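# Methods

This note documents the models, algorithms and numerical choices behind
`smlmclassify`, and what the synthetic-data studies do and do not
demonstrate.

## Problem setting

Single-molecule localization microscopy (SMLM) of repeated structures —
DNA-origami nanostructures, nuclear pore complexes (NPCs) — yields many
*particles*: picked point clouds of localizations `r_i` with
per-localization uncertainties `σ_i` (nm). Particle fusion boosts the
effective labeling by registering and pooling many particles, but
pooling structurally different particles blurs the reconstruction. The
package classifies particles into structural classes *without any
template or prior knowledge of the number or shape of the classes*,
then fuses per class.

The pipeline has four blocks, plus an optional fifth:

1. **All-to-all pairwise registration** of the N particles
   (`registration`), producing N(N−1)/2 similarity values.
2. **Metric MDS embedding** of the derived dissimilarity matrix
   (`embedding.mds_embed`).
3. **Multi-restart k-means** in the embedding (`embedding.kmeans_cluster`),
   with silhouette-based guidance for K.
4. **Per-cluster fusion** (`fusion`).
5. Optionally, **eigen-image merging** of K clusters into C < K final
   classes (`eigenmerge`), used when a small subpopulation is hunted by
   deliberate over-clustering.

## Pairwise registration

Each pair is registered by maximizing a Gaussian-mixture overlap: a
Gaussian of uniform width (the *scale*, expressed in camera pixels and
converted at 130 nm/px by default) is placed on every localization and
the overlap of the two mixtures is maximized over in-plane rotation and
translation. Reflections are never searched, so mirrored subpopulations
cannot register well and separate downstream. The search is restarted
from 6 angles uniform in [0, 2π); each start runs a Nelder–Mead over
(θ, tx, ty) initialized with the centroid-aligning translation.

Registration *quality* is then measured at each of the 6 optima with
the Bhattacharyya similarity

S(a,b) = 1/(K_a K_b) Σ_i Σ_j exp(−½‖r_{a,i} − T r_{b,j}‖²/(σ²_{a,i}+σ²_{b,j})) / (σ²_{a,i}+σ²_{b,j})

and the transform with the highest S wins. The two normalizations make
scores comparable across pairs: 1/(K_a K_b) removes the dependence on
localization counts, the variance-sum division removes the reward for
large uncertainties. In 3D with anisotropic uncertainties the exponent
is evaluated per axis (lateral σ², axial σ_z²) and the prefactor uses
the geometric mean of the per-axis variance sums; this reduces exactly
to the isotropic form when σ_z = σ, and is isolated in one kernel.

Dissimilarities are D(a,b) = max S − S(a,b), so the best-matching pair
has D = 0 and all D ≥ 0.

### Scale selection

The scale is chosen by a sweep: 10 random pairs are registered at 50
scales linearly spaced over 0.001–0.5 camera pixels (0.13–65 nm at
130 nm/px); each pair's quality curve is normalized to its own maximum,
curves are averaged, and the argmax is taken. The recorded quality is
the *Bhattacharyya similarity of the registration found at that scale*,
not the raw mixture overlap: the overlap itself varies monotonically
with the kernel width (more blur always overlaps more, and the Gaussian
normalization diverges as the scale shrinks), whereas the scale-free
similarity peaks where registrations actually succeed — too small a
scale overfits single localizations, too large a scale blurs
neighboring binding sites together. On simulated NPC rings the sweep
selects ≈ 0.08 px ≈ 10 nm, consistent with the regime reported for
experimental pore data.

### Numerical choices

* The optimizer is a Nelder–Mead written into the numba kernel;
  translations are scaled by max(scale, 2 nm) so the simplex is
  well-conditioned. Defaults: simplex-spread tolerance 5e-3, relative
  objective tolerance 1e-6, 100 objective evaluations per start. These
  recover noise-free poses to < 1° and < 0.5 nm while keeping an
  all-to-all of 500 particles (~35 localizations each) around two
  minutes single-threaded; halving the evaluation budget visibly
  degrades the similarity contrast that rare-class detection relies on.
* The search objective drops exponent terms below −10 and evaluates the
  exponential by a 4096-entry linear-interpolation table (relative
  error < 1e-6). The Bhattacharyya similarity is always evaluated with
  the exact, cutoff-free double sum.
* Pairs where either particle has < 3 localizations skip optimization
  (a 3-parameter pose is under-determined below 3 points) and are
  scored at the identity transform.
* 3D rotations are parameterized by rotation vectors; starts are 12
  axis orientations (icosahedron vertices) × 4 in-plane angles,
  generalizing the six 2D angles. The 3D path uses scipy's
  Nelder–Mead; it is intended for small studies, not 500-particle runs.
* All pair computations are independent and deterministic, so the
  all-to-all result does not depend on evaluation order or chunking.

## MDS embedding

SMACOF stress majorization (Guttman transform) initialized from the
classical (Torgerson) solution, minimizing the normalized metric stress
`sqrt(Σ(d_ij − ‖x_i−x_j‖)² / Σ d_ij²)` over unordered pairs. Stress is
non-increasing across iterations by construction (the monotone trace is
asserted in tests); iteration stops at a relative stress change below
1e-6 or 300 iterations. The default dimensionality is d = 30: on
synthetic multi-class mixtures the classification accuracy plateaus
well before d = 15, and doubling the plateau onset provides headroom
at negligible cost. d is capped at N − 1.

## k-means and silhouette

Each of the (default) 1000 restarts seeds Lloyd's algorithm with K
uniformly drawn particles; the restart with the smallest within-cluster
sum of *unsquared* point-to-centroid distances is kept (ties keep the
first, seed-ordered). For rare-class hunting, restarts should be at
least the number of particles, so every particle is on average drawn
once as an initial seed — `rare_class_trial` uses max(1000, N).

Silhouette values (b−a)/max(a,b) are computed on the first three
embedding dimensions, which carry the dominant variation; full-dimension
silhouettes are available by passing other coordinates. Singleton
clusters get value 0 (the formula is undefined there; 0 is the common
convention and keeps the mean well-defined). `suggest_K` reports the
mean silhouette per candidate K and the argmax *as a suggestion*: flat
profiles (single-class or continuously varying data) are reported
without failure, and the final choice of K is the user's.

## Per-cluster fusion

The full transform-graph-averaging fusion of the template-free particle
fusion literature is deliberately simplified: the member with the
highest mean similarity to the rest of its cluster becomes the
reference (ties break to the lowest particle id), and every other
member is mapped into its frame with the transform already stored by
the all-to-all step, so fusion is essentially free. An optional
refinement pass re-registers each member against the pooled cloud of
the others (capped at 600 localizations) and keeps the refined pose
only when it improves the similarity. The interface isolates this
choice; a full fusion backend could be swapped in without touching the
rest of the pipeline.

For regular multi-site structures (the 12-site, 20 nm 4 × 3 grid) the
raw clouds are first condensed to binding-site centers by DBSCAN
(ε = 0.03 camera pixels, minimum 4 points; Euclidean in pixel units),
each center carrying the mean uncertainty of its member localizations;
registration runs on centers, and afterwards the centers are replaced
by all original localizations, so the localization count is conserved.
DBSCAN-noise counts are recorded on the reconstruction.

## Eigen-image merging

The K cluster reconstructions are mutually aligned (registration on
random subsets of ≤ 120 localizations per reconstruction — the
double-sum objective is quadratic in cloud size — with the transforms
applied to the full clouds), rendered into a shared square frame (the
common bounding box padded 10%) as 400 × 400 count histograms, and
normalized to zero mean and unit 2-norm. As a rule of thumb, the pixel
should be about ¼ of the localization uncertainty. Two alignment
choices matter and were found the hard way:

* The reference frame is the *largest* reconstruction, not the one with
  the highest mean similarity. A tight minority cluster (e.g. a
  mirrored subpopulation) can win the similarity vote; every majority
  cluster then aligns to a frame it cannot actually match, their
  mutual alignment becomes inconsistent, and the eigen-image weights
  lose all contrast. The majority structure defines the frame; clusters
  that cannot align to it are exactly the ones that should look
  different.
* Since only K(K−1)/2 registrations are needed, the alignment step uses
  twice the angular starts (12) and a 1.5× evaluation budget relative
  to the particle-level all-to-all: near-symmetric or lattice-like
  structures have competing rotational optima that six starts can miss,
  and one mis-rotated cluster image contaminates the whole
  decomposition.

The image stack X (N_pix² × K) is decomposed through the K × K Gram
matrix XᵀX; eigenvectors a are lifted to eigen images u = X a and
re-normalized, with eigenvalues (squared singular values of X) sorted
descending. Each eigen image's sign is fixed so its projection onto the
mean input image is non-negative — the SVD sign is arbitrary and would
otherwise make the weights irreproducible. All K images are projected
onto the *first* eigen image only; the resulting 1D weights are grouped
by average-linkage hierarchical agglomerative clustering cut at exactly
C clusters. Final classes pool the aligned clusters' localizations
(with the simplified fusion above, fusing already-aligned clusters is
pooling). The pipeline applies a small Gaussian pre-blur
(`render_blur_px`, default 2 pixels ≈ ¼–1 σ at typical frames) to the
histograms before normalization: a desk-scale cluster reconstruction
puts a few hundred localizations into 160 000 pixels, and raw
renderings of the *same* structure then correlate only where
localizations hit the very same pixel — the first-eigen-image weights
become sampling noise (observed range 0.07–0.55 between structurally
identical clusters). With the blur, correlations measure blob overlap
and a structurally deviant cluster is a clear weight outlier. Set
``render_blur_px = 0`` for raw histograms, appropriate when clusters
carry thousands of localizations.

## Shape analysis

Ring ellipticity: localizations are grouped into n_sites (default 8)
blobs by k-means seeded at angularly equispaced positions around the
centroid (random seeding can split one blob); the coordinate-wise
median per blob resists imbalanced localization counts; a direct
least-squares ellipse (scikit-image's conic fit) through the medians
gives e = a/b ≥ 1 and the major-axis orientation θ ∈ [0, π). The fit is
unweighted — weighting blobs by localization count would reintroduce
the imbalance the medians remove.

Order parameter: ⟨cos 2(θ − θ̄)⟩ with the director θ̄ computed as
½·atan2(⟨sin 2θ⟩, ⟨cos 2θ⟩) — the plain average is ill-defined for
axial (period-π) angles. 1 means complete alignment; 0 is the
expectation under uniform orientations.

## Synthetic data generator

`simdata` emulates picked particle data: designed site templates (the
4 × 3 grid at 20 nm; N-fold rings, default diameter 107 nm; letter- and
digit-like dot patterns on a 20 nm lattice; a 3D tetrahedron with
100 nm edges and 90 nm apex height), observed with

* density of labeling (DoL): each site independently retained with
  probability `dol`;
* localizations per retained site: Poisson, default mean 8;
* per-localization σ: Gamma with mean 2 nm and shape 9 (CV ⅓) for
  origami-like 2D data — a plausible DNA-PAINT regime; 3D data takes a
  separate axial σ_z (mean 8 nm is the regime of experimental
  tetrahedron data); all configurable;
* pose: uniform rotation, translational jitter uniform within ±0.25 of
  the template extent (picked particles are roughly centered);
* optional mirroring (reflection of the last axis, applied before the
  pose — any fixed mirror axis is equivalent under the uniform rotation
  prior) and area-preserving elliptical deformation (√e along x, 1/√e
  along y, applied before the pose).

Noise is added in the template frame; isotropic Gaussian noise is
rotation invariant, so this is statistically identical to camera-frame
noise and makes a mirrored draw the exact reflection of its unmirrored
counterpart under the same seed. Draws with no retained site are
redrawn and logged. Mixtures draw class labels either multinomially
from the fractions or with exact largest-remainder counts; everything
is reproducible from the seed. Not emulated: blinking kinetics, drift,
PSF shape, raw camera frames — so passing tests demonstrate robustness
to underlabeling, count imbalance and localization noise, not to
correlated artifacts of real acquisitions.

## Desk-scale studies and problem sizes

The validation studies are sized to run on one CPU in minutes, as the
package's own test conditions:

* **Rare-class detection**: 500 NPC-like rings (8-fold vs 9-fold on the
  same 107 nm diameter), DoL 0.7, Poisson(6) localizations per site,
  σ ≈ 3 nm (Gamma, shape 9), exact-count mixtures. Classification uses
  K = 40 (the value used for rare-class hunting on experimental
  mirrored-origami data) followed by an eigen merge to C = 2; detection
  succeeds when the minority output class contains ≥ 80% of the true
  9-fold particles, and a condition counts as detected when ≥ 4 of 5
  seeds succeed. Ten rare particles (2%) are reliably isolated.
* **Dimensionality plateau / multi-class separability**: 200 particles,
  four classes of 12 sites each (4 × 3 grid, 12-fold ring, 2 × 6
  ladder, irregular off-lattice pattern), DoL 0.7, generator defaults
  otherwise. Matching the site counts makes the similarity magnitudes
  comparable across classes — the printed metric scales roughly
  inversely with the site count, so unequal counts would separate
  classes by magnitude rather than structure. One dissimilarity matrix
  is embedded at d ∈ {2, 5, 10, 15, 20, 30} and clustered at K = 4
  with 1000 restarts.

`scripts/acceptance.py` re-runs both studies from scratch; it sweeps
the rare-class count upward from 10 only if a level fails, and reports
the smallest successful fraction/count.

## Known limitations

* The simplified fusion has no global transform-graph consistency; for
  very heterogeneous clusters the reference choice can matter.
* The 3D registration path is ~50× more expensive per pair than the 2D
  numba path and is meant for small collections.
* The scale sweep assumes the sampled pairs are representative; on
  strongly mixed data a per-class sweep could differ.
* Silhouette-based K suggestion is known to be uninformative when
  classes vary continuously (e.g. a height continuum); the tool then
  reports a flat profile and leaves K to the user.
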