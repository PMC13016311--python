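# fodparc

Parcellation of the thalamus and its pulvinar nucleus from diffusion
MRI, using per-voxel fiber orientation distributions (FODs) as
microstructural features. The package implements a two-stage clustering
pipeline — BIRCH (CF-tree) superclustering followed by spectral
clustering on a supercluster graph — together with a combined-distance
k-means baseline, a synthetic FOD phantom generator with ground truth,
and the full evaluation battery (Dice confusion matrices, adjusted Rand
index, group probability maps, consistency statistics, Wilcoxon
comparisons).

## The problem and the model

Standard T1/T2 contrast cannot separate thalamic nuclei, but each
nucleus has a characteristic local fiber geometry. Given a 4D NIfTI
volume of real even spherical-harmonic FOD coefficients (order ≤ 6,
d = 28 per voxel, e.g. from MSMT-CSD) and a binary structure mask on
the same grid, each in-mask voxel *i* contributes a spatial coordinate
c_i ∈ R³ (mm) and a feature vector f_i ∈ R^d. Voxels are compared with
the combined metric

    D_tot(i, j) = α‖c_i − c_j‖ + γ(1 − α)‖f_i − f_j‖

with plain Euclidean norms, α = 0.5 by default, and γ a scale factor
calibrated so the mean pairwise spatial and (scaled) feature distances
coincide — the closed-form minimizer of |mean_spatial − γ·mean_feature|
is the ratio of the two means.

Clustering proceeds in two stages:

1. **Superclusters.** A CF-tree (BIRCH, branching factor 100,
   threshold 1) groups voxels by spatial proximity into m compact
   superclusters, shrinking the graph problem and damping voxel-level
   noise.
2. **Spectral partition.** Superclusters S_p, S_q are compared through
   the median of all cross-pair combined distances,
   M_pq = median { D_tot(i, j) : i ∈ S_p, j ∈ S_q }. A k-nearest-
   neighbour Gaussian affinity graph over M (bandwidth = median retained
   distance, connectivity-repaired) is partitioned with normalized
   spectral clustering (symmetric Laplacian, row-normalized embedding,
   k-means with 50 restarts), and node labels propagate back to voxels.

The baseline is a modified k-means directly on voxels under D_tot, with
a data-driven initialization stage that scores 5,000 random centroid
draws and refines the best one.

## Worked example

`examples/02_parcellate_and_evaluate.py` generates a 20³ three-region
phantom (1,416 masked voxels, each region with its own dominant fiber
orientation), runs both methods and scores them against the planted
regions:

```text
spectral: ARI vs truth = 0.773 (m=208 superclusters)
  best Dice per planted region -> region 1: 0.92, region 2: 0.93, region 3: 0.90
  calibrated gamma = 8.5
kmeans: ARI vs truth = 1.000
  best Dice per planted region -> region 1: 1.00, region 2: 1.00, region 3: 1.00
  calibrated gamma = 8.5
```

ARI is permutation-invariant, so 1.0 is perfect recovery of the planted
partition. The spectral score on a phantom this small is bounded by
supercluster granularity: every voxel inherits its supercluster's
label, so superclusters that straddle a planted boundary carry a fixed
error floor (see `docs/methods.md`). γ ≈ 8.5 reflects the small
physical extent of this toy mask; on realistically sized masks the same
calibration yields values an order of magnitude larger.

Other examples: `01_generate_phantom.py` (phantom construction and
NIfTI export), `03_gamma_calibration.py` (scale calibration and its
fixed point), `04_group_maps.py` (cross-subject harmonization, group
probability maps and consistency statistics).

A thin CLI mirrors the library:

```bash
fodparc phantom --shape 40,40,40 --regions 4 --seed 7 --out phantom/
fodparc calibrate --fod phantom/fod.nii.gz --mask phantom/mask.nii.gz
fodparc cluster --fod phantom/fod.nii.gz --mask phantom/mask.nii.gz \
        --nc 4 --method spectral --gamma auto --out labels.nii.gz
fodparc evaluate --labels labels.nii.gz --atlas phantom/truth_labels.nii.gz --out report/
fodparc group-maps --labels s1.nii.gz --labels s2.nii.gz --threshold 0.5 --out group/
```

Every run writes a JSON sidecar with the resolved configuration;
re-running `cluster` from a sidecar reproduces the label volume
bit-exactly.

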