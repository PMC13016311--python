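"""Synthetic fiber-orientation-distribution (FOD) phantoms.

Real diffusion-MRI parcellation inputs are a 4D volume of real even
spherical-harmonic (SH) coefficients inside a compact gray-matter mask.
This module generates volumes with the same statistical structure —
spatially contiguous regions, each with a distinct dominant fiber
orientation, plus additive coefficient noise — together with ground-truth
labels, so the whole clustering and evaluation stack can be exercised
without any acquired data.

The single-fiber kernel is a Watson-type density ``exp(kappa * (u.v)^2)``
normalized on the sphere and projected onto the real even SH basis by
least squares over a dense spherical point set. It is antipodally
symmetric (as FODs are) and has one sharpness knob, ``concentration``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import sph_harm_y

from .errors import InvalidArgumentError

__all__ = [
    "PhantomSpec",
    "PhantomOutput",
    "count_sh_coefficients",
    "eval_real_even_sh_basis",
    "make_region_fod",
    "generate_phantom",
    "fibonacci_sphere",
    "spread_directions",
]


def count_sh_coefficients(lmax: int) -> int:
    """Number of real even-order SH basis functions up to degree ``lmax``.

    For the even-only basis used for antipodally symmetric densities this
    is ``(lmax + 1)(lmax + 2) / 2``; order 6 gives the familiar 28
    coefficients per voxel.
    """
    lmax = int(lmax)
    if lmax < 0 or lmax % 2 != 0:
        raise InvalidArgumentError(f"lmax must be even and >= 0, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on S^2 (Fibonacci lattice)."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def spread_directions(k: int, seed: int = 0) -> np.ndarray:
    """``k`` well-separated unit directions (antipodally distinct).

    Picks points of a Fibonacci lattice restricted to the upper hemisphere,
    spaced as far apart as the lattice allows. Useful as phantom region
    directions when none are given explicitly.
    """
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    pts = fibonacci_sphere(4 * k + 8)
    upper = pts[pts[:, 2] >= 0]
    # greedy farthest-point selection on axial (antipodal-invariant) distance
    chosen = [0]
    while len(chosen) < k:
        cos2 = np.max(np.abs(upper[chosen] @ upper.T), axis=0)
        chosen.append(int(np.argmin(cos2)))
    return upper[chosen]


def eval_real_even_sh_basis(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Evaluate the real, even-order SH basis at unit ``directions``.

    Returns an ``(n_directions, d)`` matrix with ``d =
    count_sh_coefficients(lmax)``. Basis ordering is degree-major
    (l = 0, 2, ..., lmax) with m running -l..l inside each degree, the
    convention used by MRtrix-style FOD files. The real basis is built
    from the complex harmonics Y_l^m as

    * m = 0:  Y_l^0 (already real)
    * m > 0:  sqrt(2) * (-1)^m * Re(Y_l^m)
    * m < 0:  sqrt(2) * (-1)^m * Im(Y_l^|m|)

    so the l = 0 column is the constant ``1 / (2 sqrt(pi))``.
    """
    d = count_sh_coefficients(lmax)
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    if dirs.ndim != 2 or dirs.shape[1] != 3:
        raise InvalidArgumentError("directions must be (n, 3)")
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise InvalidArgumentError("directions must be unit vectors (|norm-1| <= 1e-6)")
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))  # polar angle
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    out = np.empty((dirs.shape[0], d))
    col = 0
    for ell in range(0, lmax + 1, 2):
        for m in range(-ell, ell + 1):
            y = sph_harm_y(ell, abs(m), theta, phi)
            if m == 0:
                out[:, col] = y.real
            elif m > 0:
                out[:, col] = np.sqrt(2.0) * (-1.0) ** m * y.real
            else:
                out[:, col] = np.sqrt(2.0) * (-1.0) ** m * y.imag
            col += 1
    assert col == d
    return out


# Dense sample used to project kernels onto the basis; 3000 points keeps
# the quadrature error for lmax <= 8 well below coefficient noise levels.
_PROJECTION_POINTS = 3000


def make_region_fod(
    direction: np.ndarray,
    concentration: float,
    lmax: int = 6,
    n_points: int = _PROJECTION_POINTS,
) -> np.ndarray:
    """SH coefficients of a single-fiber density peaked at ``+-direction``.

    A Watson-type kernel ``exp(kappa (u.v)^2)`` is normalized to unit mass
    on the sphere and projected onto the real even SH basis by least
    squares over a Fibonacci point set. The coefficient norm grows with
    ``concentration``; as it tends to 0 only the l = 0 coefficient
    survives (isotropic limit).
    """
    if concentration <= 0:
        raise InvalidArgumentError("concentration must be > 0")
    v = np.asarray(direction, dtype=float)
    if v.shape != (3,) or abs(np.linalg.norm(v) - 1.0) > 1e-6:
        raise InvalidArgumentError("direction must be a unit 3-vector")
    pts = fibonacci_sphere(n_points)
    w = np.exp(concentration * (pts @ v) ** 2)
    density = w / (w.mean() * 4.0 * np.pi)  # integral over S^2 == 1
    basis = eval_real_even_sh_basis(pts, lmax)
    coeffs, *_ = np.linalg.lstsq(basis, density, rcond=None)
    return coeffs


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic FOD volume.

    Attributes
    ----------
    grid_shape : (3,) ints, volume dimensions in voxels.
    voxel_size_mm : isotropic voxel edge length.
    mask_kind : ``"ellipsoid"`` or ``"box"`` — compact mask centred in the
        grid with semi-axes (or half-widths) of 40% of each dimension.
    n_regions : number of ground-truth regions K.
    region_directions : (K, 3) unit vectors, one dominant orientation each.
    concentration : Watson kernel sharpness; higher is more anisotropic.
    noise_sd : sd of i.i.d. Gaussian noise added to every SH coefficient.
    seed : RNG seed; identical specs yield bit-identical phantoms.
    sh_order : even maximum SH degree (default 6 → 28 coefficients).
    region_size_fractions : optional target volume fraction per region;
        when given, regions are grown around their seeds to approximately
        these sizes (useful for small-nucleus phantoms), otherwise a
        seeded Voronoi partition is used.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float = 1.25
    mask_kind: str = "ellipsoid"
    n_regions: int = 4
    region_directions: np.ndarray | None = None
    concentration: float = 20.0
    noise_sd: float = 0.02
    seed: int = 0
    sh_order: int = 6
    region_size_fractions: tuple[float, ...] | None = None

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise InvalidArgumentError("grid_shape must be three positive ints")
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        if self.voxel_size_mm <= 0:
            raise InvalidArgumentError("voxel_size_mm must be > 0")
        if self.mask_kind not in ("ellipsoid", "box"):
            raise InvalidArgumentError(f"unknown mask_kind {self.mask_kind!r}")
        if self.n_regions < 1:
            raise InvalidArgumentError("n_regions must be >= 1")
        if self.sh_order < 0 or self.sh_order % 2 != 0:
            raise InvalidArgumentError("sh_order must be even and >= 0")
        if self.concentration <= 0:
            raise InvalidArgumentError("concentration must be > 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        dirs = self.region_directions
        if dirs is None:
            dirs = spread_directions(self.n_regions)
        dirs = np.asarray(dirs, dtype=float)
        if dirs.shape != (self.n_regions, 3):
            raise InvalidArgumentError(
                "region_directions must be (n_regions, 3), got "
                f"{dirs.shape} with n_regions={self.n_regions}"
            )
        if np.any(np.abs(np.linalg.norm(dirs, axis=1) - 1.0) > 1e-8):
            raise InvalidArgumentError("region_directions must be unit vectors")
        object.__setattr__(self, "region_directions", dirs)
        if self.region_size_fractions is not None:
            frac = tuple(float(f) for f in self.region_size_fractions)
            if len(frac) != self.n_regions or any(f <= 0 for f in frac):
                raise InvalidArgumentError(
                    "region_size_fractions must give one positive fraction per region"
                )
            object.__setattr__(self, "region_size_fractions", frac)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region_directions"] = np.asarray(self.region_directions).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["grid_shape"] = tuple(d["grid_shape"])
        if d.get("region_directions") is not None:
            d["region_directions"] = np.asarray(d["region_directions"], dtype=float)
        if d.get("region_size_fractions") is not None:
            d["region_size_fractions"] = tuple(d["region_size_fractions"])
        return cls(**d)


@dataclass
class PhantomOutput:
    """Generated phantom: FOD volume, mask, truth labels and geometry."""

    fod: np.ndarray  # (x, y, z, d)
    mask: np.ndarray  # (x, y, z) uint8
    truth_labels: np.ndarray  # (x, y, z) int, 0 background, 1..K regions
    affine: np.ndarray  # 4x4
    spec: PhantomSpec

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write NIfTI volumes plus a JSON sidecar with the spec."""
        from . import volumes

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fod": outdir / "fod.nii.gz",
            "mask": outdir / "mask.nii.gz",
            "truth": outdir / "truth_labels.nii.gz",
            "spec": outdir / "phantom_spec.json",
        }
        volumes.write_fod(
            volumes.FodVolume(self.fod.astype(np.float32), self.affine, self.spec.sh_order),
            paths["fod"],
        )
        volumes.write_labels(
            volumes.LabeledVolume(self.mask.astype(np.int16), self.affine), paths["mask"]
        )
        volumes.write_labels(
            volumes.LabeledVolume(self.truth_labels.astype(np.int16), self.affine),
            paths["truth"],
        )
        paths["spec"].write_text(json.dumps(self.spec.to_dict(), indent=2))
        return paths


# Mask half-extents as fractions of the grid: slightly anisotropic, like
# the ovoid thalamic masks the pipeline is meant for. On a 40^3 grid the
# ellipsoid holds ~11k voxels, the per-hemisphere scale of real masks.
_MASK_HALF_FRACTIONS = np.array([0.40, 0.35, 0.30])


def _make_mask(spec: PhantomSpec) -> np.ndarray:
    shape = np.asarray(spec.grid_shape)
    center = (shape - 1) / 2.0
    half = _MASK_HALF_FRACTIONS * shape
    idx = np.indices(spec.grid_shape).reshape(3, -1).T.astype(float)
    if spec.mask_kind == "ellipsoid":
        inside = np.sum(((idx - center) / half) ** 2, axis=1) <= 1.0
    else:  # box
        inside = np.all(np.abs(idx - center) <= half, axis=1)
    return inside.reshape(spec.grid_shape).astype(np.uint8)


def _partition_regions(
    spec: PhantomSpec, voxels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Assign each in-mask voxel (rows of ``voxels``) a region 1..K."""
    n = voxels.shape[0]
    K = spec.n_regions
    seed_rows = rng.choice(n, size=K, replace=False)
    seeds = voxels[seed_rows].astype(float)
    d2 = ((voxels[:, None, :].astype(float) - seeds[None, :, :]) ** 2).sum(axis=2)
    if spec.region_size_fractions is None:
        return np.argmin(d2, axis=1) + 1
    # capacity-constrained variant: grow regions around their seeds in
    # order of increasing target size, taking each region's nearest
    # still-unassigned voxels; the last region absorbs the remainder.
    frac = np.asarray(spec.region_size_fractions, dtype=float)
    frac = frac / frac.sum()
    targets = np.round(frac * n).astype(int)
    targets[-1] = n - targets[:-1].sum()
    labels = np.zeros(n, dtype=int)
    order = np.argsort(frac, kind="stable")
    remaining = np.ones(n, dtype=bool)
    for pos, k in enumerate(order):
        if pos == len(order) - 1:
            labels[remaining] = k + 1
            break
        take = min(targets[k], int(remaining.sum()))
        cand = np.flatnonzero(remaining)
        nearest = cand[np.argsort(d2[cand, k], kind="stable")[:take]]
        labels[nearest] = k + 1
        remaining[nearest] = False
    return labels


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Build mask, ground-truth regions and noisy FOD coefficients.

    Deterministic given ``spec`` (including its seed): the region seeds,
    the partition and the coefficient noise all flow from one
    ``numpy.random.default_rng(spec.seed)`` stream.
    """
    d = count_sh_coefficients(spec.sh_order)
    mask = _make_mask(spec)
    voxels = np.argwhere(mask > 0)  # lexicographic order
    n = voxels.shape[0]
    if spec.n_regions > n:
        raise InvalidArgumentError(
            f"n_regions={spec.n_regions} exceeds mask voxel count {n}"
        )
    rng = np.random.default_rng(spec.seed)
    labels_flat = _partition_regions(spec, voxels, rng)

    region_coeffs = np.stack(
        [
            make_region_fod(spec.region_directions[k], spec.concentration, spec.sh_order)
            for k in range(spec.n_regions)
        ]
    )
    feats = region_coeffs[labels_flat - 1]
    feats = feats + rng.normal(0.0, spec.noise_sd, size=feats.shape)

    fod = np.zeros(spec.grid_shape + (d,), dtype=float)
    fod[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = feats
    truth = np.zeros(spec.grid_shape, dtype=np.int16)
    truth[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = labels_flat

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    return PhantomOutput(fod=fod, mask=mask, truth_labels=truth, affine=affine, spec=spec)
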