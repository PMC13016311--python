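"""Segmentation evaluation: Dice, ARI, group maps, consistency, statistics.

Covers the full battery used to assess parcellations against reference
atlases and across subjects:

* Dice confusion matrices between cluster supports and atlas nuclei,
  with maximum-Dice matching of nuclei to clusters;
* adjusted Rand index between voxelwise partitions (label-permutation
  invariant, robust to differing cluster counts);
* cross-subject label harmonization (Hungarian assignment on negative
  Dice against a reference) so that per-subject parcellations can be
  stacked into spatial probabilistic, maximum-probability and
  50%-thresholded group label maps;
* per-cluster consistency metrics (volume ratio, centroid distance to
  the structure boundary via a Euclidean distance transform) and their
  across-subject coefficients of variation;
* paired Wilcoxon signed-rank comparisons of per-subject scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .clustering import Parcellation
from .errors import DegenerateInputError, InvalidArgumentError, ShapeMismatchError
from .volumes import LabeledVolume

__all__ = [
    "DiceMatrix",
    "GroupMaps",
    "dice",
    "dice_confusion",
    "max_dice_match",
    "adjusted_rand_index",
    "harmonize_labels",
    "group_maps",
    "consistency_metrics",
    "consistency_summary",
    "wilcoxon_compare",
    "coefficient_of_variation",
]

logger = logging.getLogger(__name__)


@dataclass
class DiceMatrix:
    """Dice scores for every (atlas label, cluster label) pair."""

    values: np.ndarray  # (n_atlas_labels, n_cluster_labels)
    atlas_labels: np.ndarray
    cluster_labels: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.atlas_labels, name="atlas_label"),
            columns=pd.Index(self.cluster_labels, name="cluster_label"),
        )


@dataclass
class GroupMaps:
    """Across-subject label frequency maps in a common space."""

    prob: np.ndarray  # (x, y, z, n_labels) frequencies in [0, 1]
    labels: np.ndarray  # label ids for the 4th axis
    maxprob: np.ndarray  # (x, y, z) int
    thresholded: np.ndarray  # (x, y, z) int, maxprob gated at `threshold`
    threshold: float
    n_subjects: int


def _as_label_array(x) -> np.ndarray:
    if isinstance(x, Parcellation):
        return x.labels
    if isinstance(x, LabeledVolume):
        return x.data
    return np.asarray(x)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two binary volumes.

    Defined as 0 (with a log line) when both sets are empty, so absent
    nuclei never score a spurious perfect overlap.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        logger.info("dice of two empty sets defined as 0")
        return 0.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def dice_confusion(parc, atlas) -> DiceMatrix:
    """Dice of every cluster support against every atlas nucleus support."""
    p = _as_label_array(parc)
    a = _as_label_array(atlas)
    if p.shape != a.shape:
        raise ShapeMismatchError(f"shapes differ: {p.shape} vs {a.shape}")
    atlas_labels = np.unique(a[a > 0])
    cluster_labels = np.unique(p[p > 0])
    vals = np.zeros((atlas_labels.size, cluster_labels.size))
    for i, al in enumerate(atlas_labels):
        asup = a == al
        for j, cl in enumerate(cluster_labels):
            vals[i, j] = dice(asup, p == cl)
    return DiceMatrix(values=vals, atlas_labels=atlas_labels, cluster_labels=cluster_labels)


def max_dice_match(dm: DiceMatrix) -> dict[int, tuple[int, float]]:
    """Per atlas nucleus, the cluster with maximal Dice (ties -> lowest id).

    Many-to-one matches are allowed: two nuclei may share a best cluster.
    """
    if dm.values.size == 0:
        raise DegenerateInputError("empty Dice matrix")
    out: dict[int, tuple[int, float]] = {}
    for i, al in enumerate(dm.atlas_labels):
        j = int(np.argmax(dm.values[i]))  # argmax takes the first = lowest id on ties
        out[int(al)] = (int(dm.cluster_labels[j]), float(dm.values[i, j]))
    return out


def adjusted_rand_index(p: np.ndarray, q: np.ndarray) -> float:
    """Chance-corrected pairwise partition agreement in [-1, 1].

    Both inputs are flat label vectors over the same voxel set. The
    degenerate case of a single cluster in both partitions is defined as
    1 (perfect agreement), the convention also used by scikit-learn.
    """
    p = np.asarray(p).ravel()
    q = np.asarray(q).ravel()
    if p.shape != q.shape:
        raise ShapeMismatchError("partitions must have equal length")
    if p.size == 0:
        raise DegenerateInputError("empty partitions")
    return float(adjusted_rand_score(p, q))


def harmonize_labels(
    parcs: list, reference=None
) -> list[Parcellation]:
    """Relabel each subject's clusters to best match a reference.

    One-to-one maximum-Dice assignment (Hungarian algorithm on the
    negative Dice matrix) against the reference (default: the first
    subject). Clusters left unmatched when label counts differ keep
    fresh labels above the reference range. Only label names change —
    the voxelwise partition (and hence any ARI) is untouched.
    """
    if not parcs:
        raise DegenerateInputError("no parcellations to harmonize")
    ref = _as_label_array(reference if reference is not None else parcs[0])
    if not np.any(ref > 0):
        raise DegenerateInputError("reference parcellation is empty")
    ref_labels = np.unique(ref[ref > 0])
    out = []
    for parc in parcs:
        data = _as_label_array(parc)
        if data.shape != ref.shape:
            raise ShapeMismatchError("all parcellations must share the reference grid")
        if not np.any(data > 0):
            raise DegenerateInputError("cannot harmonize an empty parcellation")
        dm = dice_confusion(data, ref)  # rows: ref labels, cols: subject clusters
        rows, cols = linear_sum_assignment(-dm.values)
        mapping: dict[int, int] = {}
        for r, c in zip(rows, cols):
            mapping[int(dm.cluster_labels[c])] = int(dm.atlas_labels[r])
        fresh = int(ref_labels.max()) + 1
        for cl in dm.cluster_labels:
            if int(cl) not in mapping:
                mapping[int(cl)] = fresh
                fresh += 1
        logger.info("harmonize_labels: assignment %s", mapping)
        relabeled = np.zeros_like(data)
        for src, dst in mapping.items():
            relabeled[data == src] = dst
        if isinstance(parc, Parcellation):
            out.append(
                Parcellation(
                    labels=relabeled,
                    affine=parc.affine,
                    config=parc.config,
                    diagnostics={**parc.diagnostics, "harmonized": mapping},
                )
            )
        else:
            out.append(
                Parcellation(labels=relabeled, affine=np.eye(4), diagnostics={"harmonized": mapping})
            )
    return out


def group_maps(parcs: list, threshold: float = 0.5) -> GroupMaps:
    """Across-subject frequency, maximum-probability and thresholded maps.

    ``prob[..., k]`` is the fraction of subjects assigning label k at the
    voxel; the per-voxel sum over labels equals the fraction of subjects
    whose parcellation covers the voxel (<= 1). The maximum-probability
    map takes the most frequent label (ties -> lowest label id), and the
    thresholded map keeps only voxels whose winning frequency is at
    least ``threshold``.
    """
    if not parcs:
        raise DegenerateInputError("need at least one subject")
    arrays = [_as_label_array(p) for p in parcs]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ShapeMismatchError("all subjects must share one grid")
    labels = np.unique(np.concatenate([np.unique(a[a > 0]) for a in arrays if np.any(a > 0)]))
    if labels.size == 0:
        raise DegenerateInputError("all subject parcellations are empty")
    n_sub = len(arrays)
    prob = np.zeros(shape + (labels.size,))
    for a in arrays:
        for k, lab in enumerate(labels):
            prob[..., k] += a == lab
    prob /= n_sub
    best = np.argmax(prob, axis=-1)  # first (lowest label) wins ties
    best_freq = np.take_along_axis(prob, best[..., None], axis=-1)[..., 0]
    maxprob = np.where(best_freq > 0, labels[best], 0).astype(np.int32)
    thresholded = np.where(best_freq >= threshold, maxprob, 0).astype(np.int32)
    return GroupMaps(
        prob=prob,
        labels=labels,
        maxprob=maxprob,
        thresholded=thresholded,
        threshold=float(threshold),
        n_subjects=n_sub,
    )


def _boundary_distance_mm(mask: np.ndarray, voxel_sizes: np.ndarray) -> np.ndarray:
    """EDT of the mask (mm): distance to the nearest background voxel.

    The volume is padded with one background voxel so that the structure
    touching the array edge still has a finite boundary distance.
    """
    padded = np.pad(mask.astype(bool), 1)
    edt = scipy.ndimage.distance_transform_edt(padded, sampling=voxel_sizes)
    return edt[1:-1, 1:-1, 1:-1]


def consistency_metrics(parc, structure_mask: np.ndarray, affine=None, labels=None) -> pd.DataFrame:
    """Per-cluster volume ratio and centroid-to-boundary distance (mm).

    The centroid is the mean voxel position of the cluster rounded to the
    nearest in-mask voxel; the boundary distance is the mask's Euclidean
    distance transform at that voxel, scaled to mm via the affine.
    Empty clusters are recorded as missing (NaN), not zero.
    """
    data = _as_label_array(parc)
    mask = np.asarray(structure_mask).astype(bool)
    if data.shape != mask.shape:
        raise ShapeMismatchError("parcellation and mask grids differ")
    if affine is None:
        affine = parc.affine if isinstance(parc, Parcellation) else np.eye(4)
    voxel_sizes = np.linalg.norm(np.asarray(affine, float)[:3, :3], axis=0)
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise DegenerateInputError("structure mask is empty")
    edt = _boundary_distance_mm(mask, voxel_sizes)
    mask_voxels = np.argwhere(mask)
    if labels is None:
        if isinstance(parc, Parcellation) and parc.config is not None:
            labels = np.arange(1, parc.config.nc + 1)
        else:
            labels = np.unique(data[data > 0])
    rows = []
    for lab in labels:
        support = data == lab
        n_vox = int(support.sum())
        if n_vox == 0:
            rows.append({"label": int(lab), "volume_ratio": np.nan,
                         "centroid_boundary_distance_mm": np.nan})
            continue
        centroid = np.argwhere(support).mean(axis=0)
        nearest = mask_voxels[np.argmin(((mask_voxels - centroid) ** 2).sum(axis=1))]
        rows.append(
            {
                "label": int(lab),
                "volume_ratio": n_vox / n_mask,
                "centroid_boundary_distance_mm": float(edt[tuple(nearest)]),
            }
        )
    return pd.DataFrame(rows).set_index("label")


def consistency_summary(per_subject: list[pd.DataFrame]) -> pd.DataFrame:
    """Across-subject mean and coefficient of variation of each metric."""
    if not per_subject:
        raise DegenerateInputError("no subjects")
    stacked = pd.concat(per_subject, keys=range(len(per_subject)), names=["subject"])
    out = {}
    for col in ("volume_ratio", "centroid_boundary_distance_mm"):
        grp = stacked[col].groupby(level="label")
        out[f"{col}_mean"] = grp.mean()
        out[f"{col}_cv"] = grp.apply(
            lambda v: coefficient_of_variation(v.dropna().to_numpy())
            if v.dropna().size >= 2 and v.dropna().mean() != 0
            else np.nan
        )
    return pd.DataFrame(out)


def wilcoxon_compare(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-subject scores.

    Zero differences are dropped (Wilcoxon convention); at least five
    nonzero pairs are required for a meaningful test.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ShapeMismatchError("paired score vectors must have equal length")
    diffs = b - a
    nz = diffs[diffs != 0]
    if nz.size == 0:
        raise DegenerateInputError("all paired differences are zero; test undefined")
    if nz.size < 5:
        raise DegenerateInputError(
            f"only {nz.size} nonzero differences; need >= 5 for the signed-rank test"
        )
    res = scipy.stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def coefficient_of_variation(values) -> float:
    """Sample standard deviation divided by the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateInputError("need at least two values")
    mean = v.mean()
    if mean == 0:
        raise DegenerateInputError("coefficient of variation undefined for zero mean")
    return float(v.std(ddof=1) / mean)
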