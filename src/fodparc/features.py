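"""Per-voxel feature extraction and gamma (spatial/feature scale) calibration.

Each in-mask voxel i contributes a spatial coordinate c_i in mm and an SH
coefficient vector f_i in R^d. Because coordinate distances (mm, order
10) and FOD coefficient distances (order 0.1) live on different scales,
the combined metric multiplies feature distances by a scale factor gamma
chosen so that the mean pairwise spatial distance and gamma times the
mean pairwise feature distance coincide. The minimizer of
``|mean_spatial - gamma * mean_feature|`` is the closed-form ratio of the
two means, which is what :func:`calibrate_gamma` returns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError
from .volumes import FodVolume, LabeledVolume, check_same_grid, voxel_to_world

__all__ = ["VoxelFeatureSet", "extract_features", "calibrate_gamma"]

DEFAULT_N_PAIRS = 100_000


@dataclass
class VoxelFeatureSet:
    """Masked voxels with aligned spatial and FOD feature records.

    Rows are in fixed lexicographic voxel-index order so that every
    downstream stage is reproducible. ``grid_shape``/``affine`` carry the
    source geometry so label volumes can be reconstructed.
    """

    voxel_indices: np.ndarray  # (n, 3) int
    coords: np.ndarray  # (n, 3) float, mm
    features: np.ndarray  # (n, d) float
    lmax: int
    grid_shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        n = self.voxel_indices.shape[0]
        if n < 1:
            raise DegenerateInputError("feature set must contain at least one voxel")
        if self.coords.shape != (n, 3) or self.features.shape[0] != n:
            raise InvalidArgumentError("coords/features must align with voxel_indices")
        if not np.all(np.isfinite(self.features)):
            raise InvalidArgumentError("features must be finite")

    @property
    def n(self) -> int:
        return self.voxel_indices.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]


def extract_features(fod: FodVolume, mask: LabeledVolume) -> VoxelFeatureSet:
    """One record per nonzero-mask voxel, lexicographic voxel order."""
    check_same_grid(fod, mask)
    idx = np.argwhere(mask.data > 0)
    if idx.shape[0] == 0:
        raise DegenerateInputError("mask contains no voxels")
    coords = voxel_to_world(fod, idx)
    feats = fod.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
    return VoxelFeatureSet(
        voxel_indices=idx,
        coords=np.asarray(coords, dtype=float),
        features=feats,
        lmax=fod.lmax,
        grid_shape=fod.grid_shape,
        affine=np.asarray(fod.affine, dtype=float),
    )


def _sample_pairs(n: int, n_pairs: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    total = n * (n - 1) // 2
    if total <= n_pairs:
        return np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_pairs)
    # offset trick keeps j != i while staying uniform over ordered pairs
    j = (i + rng.integers(1, n, size=n_pairs)) % n
    return i, j


def calibrate_gamma(
    fs: VoxelFeatureSet, n_pairs: int = DEFAULT_N_PAIRS, seed: int = 0
) -> float:
    """Scale factor equalizing mean spatial and mean feature distances.

    Uses all voxel pairs when there are at most ``n_pairs`` of them,
    otherwise a seeded uniform sample of ``n_pairs`` pairs (the same
    pairs enter both means). Scale-equivariant: scaling features by s
    scales gamma by 1/s, scaling coordinates by s scales gamma by s.
    """
    if fs.n < 2:
        raise DegenerateInputError("need at least two voxels to calibrate gamma")
    if n_pairs < 1:
        raise InvalidArgumentError("n_pairs must be >= 1")
    i, j = _sample_pairs(fs.n, int(n_pairs), seed)
    mean_spatial = float(np.mean(np.linalg.norm(fs.coords[i] - fs.coords[j], axis=1)))
    mean_feature = float(np.mean(np.linalg.norm(fs.features[i] - fs.features[j], axis=1)))
    if mean_feature <= 0.0:
        raise DegenerateInputError(
            "all sampled feature vectors are identical; gamma is undefined"
        )
    return mean_spatial / mean_feature
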