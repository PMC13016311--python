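# Methods

## Feature model

Each in-mask voxel carries a spatial coordinate c_i (mm, obtained by
applying the NIfTI affine to the 0-based voxel index) and a feature
vector f_i of real even spherical-harmonic (SH) coefficients describing
its fiber orientation distribution. The even-only basis of order lmax
has d = (lmax+1)(lmax+2)/2 functions (28 at lmax = 6); it is
antipodally symmetric, as FODs are. Basis ordering is degree-major with
m = −l..l inside each degree; the real basis is assembled from the
complex harmonics (m = 0 real part; |m| > 0 via √2·(−1)^m times the
real or imaginary part), so the l = 0 column is the constant 1/(2√π).

Voxels are compared with the combined metric

    D_tot(i, j) = α‖c_i − c_j‖ + γ(1 − α)‖f_i − f_j‖,

a weighted sum of *non-squared* Euclidean norms, hence itself a metric
for α ∈ (0, 1], γ > 0 (asserted on random triples in the tests).

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| α | 0.5 | – | spatial vs feature weight |
| γ | `"auto"` | mm per feature-unit | rescales feature distances to spatial range |
| BIRCH branching B | 100 | entries | CF-tree node capacity |
| BIRCH threshold T | 1.0 | voxels (configurable: mm) | max RMS radius of a leaf entry |
| k_nn | 10 | neighbours | affinity graph sparsity |
| σ rule | `median_knn` | – | Gaussian bandwidth = median retained distance |
| nc | required | clusters | no default; the application dictates it |
| n_init_kmeans | 5000 | draws | baseline initialization budget |

γ calibration returns the exact minimizer of
|mean_spatial − γ·mean_feature| over sampled voxel pairs: the ratio of
the two means. All pairs are used up to 100,000; beyond that a seeded
uniform sample of pairs (identical pairs in both means). The estimate
is scale-equivariant and deterministic given the seed. No further
normalization is applied to the SH coefficients.

## Stage 1: CF-tree superclusters

Points (voxel positions only) are inserted one at a time in fixed
lexicographic voxel order. The closest leaf entry absorbs a point when
the merged entry's RMS radius (√(SS/n − ‖LS/n‖²)) stays ≤ T; otherwise
a new entry is created; nodes exceeding B entries split by
farthest-pair seeding. There is no global refinement pass, so each
entry's member set is exactly what it absorbed and its recomputed
radius obeys the threshold by construction (asserted in tests). The
fixed insertion order replaces data-order dependence and makes the
stage bit-reproducible.

The threshold criterion (RMS radius), the coordinate units (voxel
indices by default, mm optional) and the absence of a refinement pass
are deliberate single choices among the standard CF-tree variants; the
unit flag exists because the two readings differ measurably (T = 1
gives m ≈ 1,650 superclusters in voxel units and m ≈ 2,650 in mm units
on the 11k-voxel reference phantom). With ~10⁴ in-mask voxels,
supercluster sizes average ≈ 7 voxels.

## Stage 2: median-distance graph and spectral partition

Supercluster pairs are compared by the median of all cross-pair
combined distances (median of an even-sized multiset = mean of the two
middle values, making the brute-force oracle exact). Medians are robust
to the occasional boundary voxel that a mean would drag. The affinity
graph keeps each node's k_nn smallest distances, applies a Gaussian
kernel exp(−M²/(2σ²)) with σ the median retained distance (scale-free;
a fixed σ is available), symmetrizes by max(W, Wᵀ), and — because
spectral clustering on a disconnected graph silently returns its
components — repairs disconnection by repeatedly adding the single
minimal-distance edge between a component and the rest, logging each
repair.

The spectral step uses the symmetric normalized Laplacian
L = I − D^(−1/2) W D^(−1/2), the eigenvectors of the nc smallest
eigenvalues, row-normalization of the embedding, and Euclidean k-means
(k-means++ seeding, 50 restarts, fixed seed). Plain Euclidean k-means
in the embedding is used, not the combined metric. A dense symmetric
eigensolver serves graphs up to 3,000 nodes; above that a shift-invert
Lanczos solver takes over. Voxels inherit their supercluster's label.

With `use_birch_init=False` the same graph construction runs on voxels
directly (every voxel a singleton node). This is quadratic in the voxel
count and intended for small masks and ablation studies; on a 500-voxel
phantom it recovers the planted partition exactly, which isolates the
effect of the supercluster stage (below).

## Baseline: combined-distance k-means

The baseline clusters voxels directly under D_tot. Initialization draws
`n_init_kmeans` random centroid sets (nc distinct voxels each), scores
each with a single assignment pass (Σ_i D_tot(i, nearest centroid)),
and refines only the best draw by alternating assignment and
component-wise mean updates of (c, f). Because D_tot uses non-squared
norms, the mean update is not guaranteed to decrease the objective
monotonically; the loop therefore stops on assignment stability (or
max_iter = 100), the per-iteration objective is recorded in the
diagnostics, and the tests assert only that the final objective does
not exceed the best initialization score. Empty clusters are re-seeded
at the voxel farthest from its assigned centroid. "5,000 iterations"
of initialization is interpreted as 5,000 scored random draws followed
by one refinement from the best — the reading most consistent with a
search for good starting centroids.

## Synthetic phantom

The phantom emulates the statistical structure the method assumes: a
compact mask (ellipsoid with half-extents 40/35/30 % of the grid —
~11.3k voxels at 40³, the per-hemisphere scale of real masks — or a
box), partitioned into K spatially contiguous regions by seeded Voronoi
assignment (seeds drawn without replacement from the in-mask voxels),
each region filled with the SH projection of a Watson-type single-fiber
density exp(κ(u·v)²) normalized on the sphere, plus i.i.d. Gaussian
noise on every coefficient. Projection uses least squares over a
3,000-point Fibonacci lattice; at lmax = 6 the basis Gram matrix under
a 10,000-point lattice deviates from identity by ~6×10⁻⁶, far below
the phantom noise floor. Defaults κ = 20 (strongly anisotropic,
coefficient norm ≈ 1.1) and noise sd = 0.02 (small against
inter-region coefficient distances ≈ 1.2) represent the
high-separability regime; κ → 0 gives an isotropic negative control in
which regions are indistinguishable by features. An optional
`region_size_fractions` field grows regions to target volumes
(capacity-constrained nearest-seed growth), used to plant a small
distinct "nucleus" at ~2 % of the mask.

What the phantom does *not* emulate: spatially smooth FOD variation
within a nucleus, partial-volume mixing at boundaries, multi-fiber
voxels, spatially correlated noise, or inter-subject anatomical
variability. Passing recovery tests therefore demonstrates the
pipeline's correctness and its behavior under idealized contrast, not
expected accuracy on acquired data.

## The supercluster granularity ceiling

Because stage 2 assigns labels to whole superclusters, any voxel inside
a supercluster that straddles a planted region boundary can only
receive the majority label. Majority-vote propagation is therefore an
upper bound on the voxelwise agreement of *any* stage-2 labeling. On
the 40³ reference phantom at T = 1 (voxel units), ~4–5 % of voxels sit
in straddling superclusters, and the measured spectral ARI coincides
with this bound to the third decimal — the spectral stage operates at
its ceiling (asserted in the tests), and the residual disagreement is a
property of the supercluster quantization, not of the graph
construction or the eigensolver. Finer thresholds raise the ceiling at
the cost of a larger graph; the voxel-level ablation (no superclusters)
removes it entirely. The k-means baseline, which labels voxels
individually, recovers the separable phantom exactly in most seeds but
occasionally converges to a poor local optimum despite the 5,000-draw
initialization — the initialization sensitivity that motivates the
spectral design in the first place.

## Evaluation conventions

* Dice of two empty supports is defined as 0 (logged), so absent nuclei
  never score perfect overlap.
* Maximum-Dice matching of atlas nuclei to clusters allows many-to-one
  matches; ties break to the lowest cluster id (logged).
* ARI follows the standard contingency-table form; the degenerate case
  of one cluster in both partitions is defined as 1.
* Cross-subject label harmonization — needed before any group map —
  uses one-to-one Hungarian assignment on the negative Dice matrix
  against a reference (first subject by default); unmatched clusters
  keep fresh labels. Harmonization only renames labels; ARI is
  invariant to it.
* Group maps: per-voxel label frequencies across subjects (their sum
  equals the coverage fraction), maximum-probability map with ties to
  the lowest label id, and a thresholded map keeping voxels whose
  winning frequency is ≥ 50 % by default.
* Consistency metrics per cluster: volume ratio (cluster voxels / mask
  voxels) and the centroid-to-boundary distance in mm, read from the
  Euclidean distance transform of the mask (padded by one background
  voxel so structures touching the array edge stay finite) at the
  cluster centroid rounded to the nearest in-mask voxel. Across-subject
  variability is summarized by coefficients of variation (sample sd /
  mean). Empty clusters are reported as missing, not zero.
* Paired method comparisons use the two-sided Wilcoxon signed-rank test
  with zero differences dropped; at least five nonzero pairs are
  required.

## Numerical choices and degenerate inputs

* The squared-radius absorb test tolerates 10⁻⁹ of floating-point
  cancellation; radii recomputed from members still satisfy T within
  10⁻⁹.
* Gaussian edge weights that underflow to zero are kept as 10⁻¹²
  bridges during connectivity repair so the repair loop terminates.
* σ = 0 (all retained distances zero) falls back to unit weights.
* Embedding rows of zero norm (isolated numerical degeneracies) are
  left unnormalized rather than divided by zero.
* A parcellation missing one of its nc labels is returned with a
  `degenerate_missing_labels` diagnostic and a warning rather than an
  exception.
* All randomness flows from explicit integer seeds: the phantom RNG,
  the pair sampler, the k-means initialization draws, and the spectral
  k-means restarts. Identically-seeded reruns are bit-identical end to
  end (asserted in tests).

## Problem sizes used in the test and acceptance runs

Fast tests use 20³ phantoms (~1.4k voxels); recovery studies use 40³
phantoms (~11.3k voxels, four regions, ten seeds per study) — chosen to
exercise the same granularity regime as one thalamic hemisphere at
1.25 mm. The acceptance script's brute-force oracle instances stay at
n ≤ 100 voxels where exhaustive cross-pair enumeration is exact and
cheap.
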