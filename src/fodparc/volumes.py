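"""NIfTI volume I/O with explicit coordinate conventions.

Voxel indexing is 0-based throughout; world coordinates are millimetres
obtained through the NIfTI affine. No resampling or registration happens
here — volumes entering one clustering run must already share grid shape
and affine, and this is asserted rather than repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import BoundsError, FormatError, ShapeMismatchError
from .phantom import count_sh_coefficients

__all__ = [
    "FodVolume",
    "LabeledVolume",
    "read_fod",
    "write_fod",
    "read_labels",
    "write_labels",
    "read_label_table",
    "write_label_table",
    "voxel_to_world",
    "world_to_voxel",
    "check_same_grid",
    "infer_lmax",
]

_MAX_LMAX = 40  # generous upper bound when inferring lmax from d


@dataclass
class FodVolume:
    """4D volume of real even SH coefficients plus geometry."""

    data: np.ndarray  # (x, y, z, d)
    affine: np.ndarray  # 4x4
    lmax: int

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise FormatError("FOD data must be 4D (x, y, z, coefficients)")
        d = count_sh_coefficients(self.lmax)
        if self.data.shape[3] != d:
            raise FormatError(
                f"FOD has {self.data.shape[3]} coefficients but lmax={self.lmax} needs {d}"
            )
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class LabeledVolume:
    """3D integer label volume; 0 is reserved for background."""

    data: np.ndarray
    affine: np.ndarray
    label_names: dict[int, str] | None = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError("label data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise FormatError("label data must be integer-typed")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise FormatError("affine must be an invertible 4x4 matrix")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape


def infer_lmax(d: int) -> int:
    """Even lmax with ``(lmax+1)(lmax+2)/2 == d``, or FormatError."""
    for lmax in range(0, _MAX_LMAX + 1, 2):
        if count_sh_coefficients(lmax) == d:
            return lmax
    raise FormatError(f"{d} is not a valid even-order SH coefficient count")


def read_fod(path: str | Path) -> FodVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 4:
        raise FormatError(f"expected a 4D FOD volume, got {data.ndim}D in {path}")
    lmax = infer_lmax(data.shape[3])
    return FodVolume(data=data, affine=np.asarray(img.affine), lmax=lmax)


def write_fod(vol: FodVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def read_labels(path: str | Path) -> LabeledVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D label volume, got {data.ndim}D in {path}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise FormatError(f"label volume {path} holds non-integer values")
        data = rounded
    return LabeledVolume(data=data.astype(np.int32), affine=np.asarray(img.affine))


def write_labels(vol: LabeledVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.int16), vol.affine)
    nib.save(img, str(path))


def read_label_table(path: str | Path) -> dict[int, str]:
    """Read a two-column ``label<TAB>name`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["label", "name"], comment="#")
    return {int(r.label): str(r.name) for r in df.itertuples()}


def write_label_table(names: dict[int, str], path: str | Path) -> None:
    pd.DataFrame(sorted(names.items()), columns=["label", "name"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def voxel_to_world(volume, indices: np.ndarray) -> np.ndarray:
    """Map 0-based voxel indices to mm coordinates via the affine.

    ``volume`` may be a FodVolume/LabeledVolume or a bare 4x4 affine (in
    which case no bounds check is possible and none is done).
    """
    if hasattr(volume, "affine"):
        affine = np.asarray(volume.affine, dtype=float)
        shape = volume.grid_shape
    else:
        affine = np.asarray(volume, dtype=float)
        shape = None
    idx = np.atleast_2d(np.asarray(indices))
    if idx.shape[-1] != 3:
        raise ShapeMismatchError("indices must be (..., 3)")
    if shape is not None:
        if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
            raise BoundsError(f"voxel index outside grid of shape {shape}")
    coords = idx @ affine[:3, :3].T + affine[:3, 3]
    return coords if np.asarray(indices).ndim == 2 else coords[0]


def world_to_voxel(affine: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voxel_to_world`; returns float voxel coordinates."""
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    out = pts @ inv[:3, :3].T + inv[:3, 3]
    return out if np.asarray(coords).ndim == 2 else out[0]


def check_same_grid(a, b) -> None:
    """Raise ShapeMismatchError unless a and b share grid shape and affine."""
    if tuple(a.grid_shape) != tuple(b.grid_shape):
        raise ShapeMismatchError(f"grid shapes differ: {a.grid_shape} vs {b.grid_shape}")
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise ShapeMismatchError("affines differ between volumes")
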