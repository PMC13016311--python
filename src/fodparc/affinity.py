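"""Combined spatial + FOD metric, median supercluster distances, affinity graph.

The voxel-level metric is

    D_tot(i, j) = alpha * ||c_i - c_j|| + gamma * (1 - alpha) * ||f_i - f_j||

with plain (non-squared) Euclidean norms, c in mm and f the SH
coefficient vector. Being a weighted sum of metrics it is itself a
metric for alpha in (0, 1] and gamma > 0.

Superclusters S_p, S_q are compared through the median of all cross-pair
voxel distances,

    M_pq = median { D_tot(i, j) | i in S_p, j in S_q },

which is robust to boundary voxels that a mean would drag. Spectral
clustering then runs on a k-nearest-neighbour graph over M with a
Gaussian kernel; by default the bandwidth is the median of the retained
kNN distances, a scale-free choice. If the kNN graph is disconnected
it is repaired by adding the single minimal-distance edge between
components (repeated until connected), because spectral clustering on a
disconnected graph would silently return the components themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .errors import InvalidArgumentError, ShapeMismatchError
from .features import VoxelFeatureSet
from .superclusters import SuperclusterSet

__all__ = [
    "CombinedMetricConfig",
    "DistanceMatrix",
    "AffinityGraph",
    "combined_distance",
    "pairwise_combined_distance",
    "median_distance_matrix",
    "knn_affinity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CombinedMetricConfig:
    """alpha balances spatial vs feature terms; gamma rescales features."""

    alpha: float = 0.5
    gamma: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidArgumentError("alpha must lie in [0, 1]")
        if self.gamma <= 0:
            raise InvalidArgumentError("gamma must be > 0")


@dataclass
class DistanceMatrix:
    """Symmetric m x m median inter-supercluster distance matrix."""

    M: np.ndarray
    config: CombinedMetricConfig

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ShapeMismatchError("M must be square")
        if not np.allclose(M, M.T, atol=1e-9):
            raise InvalidArgumentError("M must be symmetric")
        self.M = M

    @property
    def m(self) -> int:
        return self.M.shape[0]


@dataclass
class AffinityGraph:
    """Sparse symmetric non-negative affinity over supercluster nodes."""

    W: sp.csr_matrix
    k_nn: int
    sigma: float
    n_repaired_edges: int = field(default=0)

    @property
    def m(self) -> int:
        return self.W.shape[0]


def combined_distance(c_i, f_i, c_j, f_j, cfg: CombinedMetricConfig) -> float:
    """D_tot between two voxels; see module docstring."""
    c_i, c_j = np.asarray(c_i, float), np.asarray(c_j, float)
    f_i, f_j = np.asarray(f_i, float), np.asarray(f_j, float)
    if c_i.shape != c_j.shape or f_i.shape != f_j.shape:
        raise ShapeMismatchError("coordinate/feature dimensions must match")
    spatial = float(np.linalg.norm(c_i - c_j))
    feature = float(np.linalg.norm(f_i - f_j))
    return cfg.alpha * spatial + cfg.gamma * (1.0 - cfg.alpha) * feature


def pairwise_combined_distance(
    coords_a, feats_a, coords_b, feats_b, cfg: CombinedMetricConfig
) -> np.ndarray:
    """Dense (|A|, |B|) matrix of D_tot values (vectorized)."""
    if coords_a.shape[1] != coords_b.shape[1] or feats_a.shape[1] != feats_b.shape[1]:
        raise ShapeMismatchError("coordinate/feature dimensions must match")
    out = cfg.alpha * cdist(coords_a, coords_b)
    if cfg.alpha < 1.0:
        out += cfg.gamma * (1.0 - cfg.alpha) * cdist(feats_a, feats_b)
    return out


def median_distance_matrix(
    fs: VoxelFeatureSet, sc: SuperclusterSet, cfg: CombinedMetricConfig
) -> DistanceMatrix:
    """Median-of-cross-pairs distances between all supercluster pairs.

    The median of an even-sized multiset is the mean of the two middle
    values (numpy convention), and the diagonal is defined as 0.
    Computed block-wise: for each supercluster p, distances from its
    members to all voxels of later superclusters, then one median per
    (p, q) block.
    """
    if sc.assignment.shape[0] != fs.n:
        raise ShapeMismatchError("supercluster assignment length does not match voxel count")
    m = sc.m
    order = np.argsort(sc.assignment, kind="stable")
    sizes = sc.sizes()
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    coords = fs.coords[order]
    feats = fs.features[order]
    M = np.zeros((m, m))
    for p in range(m - 1):
        rows = slice(offsets[p], offsets[p + 1])
        rest = slice(offsets[p + 1], offsets[m])
        D = pairwise_combined_distance(
            coords[rows], feats[rows], coords[rest], feats[rest], cfg
        )
        base = offsets[p + 1]
        s_p = sizes[p]
        qs = np.arange(p + 1, m)
        qsizes = sizes[qs]
        # medians vectorize per distinct block width: all q of size s give
        # one (s_p, n_q, s) stack with a single median call over (0, 2)
        for s in np.unique(qsizes):
            sel = qs[qsizes == s]
            starts = offsets[sel] - base
            cols = (starts[:, None] + np.arange(s)[None, :]).ravel()
            block = D[:, cols].reshape(s_p, sel.size, s)
            med = np.median(block, axis=(0, 2))
            M[p, sel] = med
            M[sel, p] = med
    return DistanceMatrix(M=M, config=cfg)


def knn_affinity(
    dm: DistanceMatrix,
    k_nn: int = 10,
    sigma_rule: str = "median_knn",
    sigma_value: float | None = None,
) -> AffinityGraph:
    """Gaussian-kernel k-nearest-neighbour graph over the distance matrix.

    Each node keeps its ``k_nn`` smallest off-diagonal distances; edge
    weights are ``exp(-M_pq^2 / (2 sigma^2))`` with sigma the median of
    all retained distances (``median_knn``) or a fixed value. The graph
    is symmetrized with max(W, W^T) and repaired to a single connected
    component by bridging nearest components with their minimal-M edge.
    """
    m = dm.m
    if not 1 <= k_nn < m:
        raise InvalidArgumentError(f"k_nn must satisfy 1 <= k_nn < m={m}")
    M = dm.M
    big = np.inf
    Moff = M + np.where(np.eye(m, dtype=bool), big, 0.0)
    nbr = np.argpartition(Moff, kth=k_nn - 1, axis=1)[:, :k_nn]
    rows = np.repeat(np.arange(m), k_nn)
    cols = nbr.ravel()
    dists = M[rows, cols]

    if sigma_rule == "median_knn":
        sigma = float(np.median(dists))
    elif sigma_rule == "fixed":
        if sigma_value is None or sigma_value <= 0:
            raise InvalidArgumentError("fixed sigma_rule requires positive sigma_value")
        sigma = float(sigma_value)
    else:
        raise InvalidArgumentError("sigma_rule must be 'median_knn' or 'fixed'")
    if sigma <= 0:
        sigma = 1.0  # all retained distances zero: uniform unit weights

    w = np.exp(-(dists**2) / (2.0 * sigma**2))
    W = sp.coo_matrix((w, (rows, cols)), shape=(m, m)).tocsr()
    W = W.maximum(W.T)
    W.setdiag(0.0)
    W.eliminate_zeros()

    n_repairs = 0
    while True:
        n_comp, labels = connected_components(W, directed=False)
        if n_comp == 1:
            break
        # bridge the component containing node 0 candidates: for each
        # component, find its globally closest outside node and add that edge
        comp0 = labels == labels[0]
        sub = M[np.ix_(comp0, ~comp0)]
        i_loc, j_loc = np.unravel_index(np.argmin(sub), sub.shape)
        i = np.flatnonzero(comp0)[i_loc]
        j = np.flatnonzero(~comp0)[j_loc]
        # floor keeps the bridge a stored nonzero even if the kernel underflows
        wij = max(np.exp(-(M[i, j] ** 2) / (2.0 * sigma**2)), 1e-12)
        W = W.tolil()
        W[i, j] = max(W[i, j], wij)
        W[j, i] = max(W[j, i], wij)
        W = W.tocsr()
        n_repairs += 1
        logger.info("affinity graph repair: bridged nodes %d-%d (M=%.4g)", i, j, M[i, j])

    return AffinityGraph(W=W, k_nn=int(k_nn), sigma=sigma, n_repaired_edges=n_repairs)
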