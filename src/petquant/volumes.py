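"""Volume containers, NIfTI-1 I/O, resampling and masked reduction.

Every image in the pipeline travels as a :class:`Volume3D` — a scalar field
on a regular 3-D grid with a 4x4 index->world affine (RAS+ millimetres) and
a declared unit label (``kBq/mL``, ``suv``, ``suvt``, ``probability``,
``t-score`` ...).  Binary regions of interest are :class:`BinaryMask`.

Design rules enforced here and relied on everywhere else:

* voxel indices are 0-based; the affine maps index -> world mm;
* inter-volume operations demand an *exact* grid match (shape equal,
  affine within 1e-4 mm) — the pipeline resamples explicitly, never
  silently;
* scalar data is float32 on disk, masks uint8;
* NaNs are rejected at the door: a NaN voxel on input is an error, and no
  operation in the package produces one.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume3D",
    "BinaryMask",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "resample_to_grid",
    "voi_mean",
]

#: absolute tolerance (mm) when comparing affines of two grids
AFFINE_ATOL_MM = 1e-4


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True, eq=False)
class Volume3D:
    """A scalar field on a regular 3-D grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.  Must be finite.
    affine : ndarray, shape (4, 4)
        0-based voxel index -> world-mm map (RAS+ convention).
    units : str
        Physical meaning of the voxel values.
    """

    data: np.ndarray
    affine: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got {data.ndim}-D data")
        n_bad = int(np.count_nonzero(~np.isfinite(data)))
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        if np.any(spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        object.__setattr__(self, "_spacing", spacing)

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return self._spacing  # type: ignore[attr-defined]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "Volume3D", atol: float = AFFINE_ATOL_MM) -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_grid(self, other: "Volume3D", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} are not on the same grid: "
                f"shapes {self.data.shape} vs {other.data.shape}"
            )

    def with_data(self, data: np.ndarray, units: str | None = None) -> "Volume3D":
        return Volume3D(data, self.affine, self.units if units is None else units)

    def world_extent(self) -> np.ndarray:
        """(3, 2) min/max world-mm coordinates of the grid's voxel centres."""
        idx = np.array(np.meshgrid(*[[0, n - 1] for n in self.data.shape])).reshape(3, -1)
        pts = self.affine[:3, :3] @ idx + self.affine[:3, 3:4]
        return np.stack([pts.min(axis=1), pts.max(axis=1)], axis=1)


@dataclass(frozen=True, eq=False)
class BinaryMask(Volume3D):
    """A Volume3D restricted to {0, 1}; defines a volume of interest."""

    region_name: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.isin(data, (0, 1)).all():
            raise ValueError("mask voxels must be exactly 0 or 1")
        object.__setattr__(self, "data", data.astype(np.uint8))
        super().__post_init__()

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    # -- small set algebra used throughout the masking module -------------
    def intersect(self, other: "BinaryMask", name: str = "") -> "BinaryMask":
        self.require_same_grid(other, "masks")
        return BinaryMask(self.data & other.data, self.affine, "mask",
                          region_name=name or f"{self.region_name}&{other.region_name}")

    def union(self, other: "BinaryMask", name: str = "") -> "BinaryMask":
        self.require_same_grid(other, "masks")
        return BinaryMask(self.data | other.data, self.affine, "mask",
                          region_name=name or f"{self.region_name}|{other.region_name}")

    def minus(self, other: "BinaryMask", name: str = "") -> "BinaryMask":
        self.require_same_grid(other, "masks")
        return BinaryMask(self.data & (1 - other.data), self.affine, "mask",
                          region_name=name or self.region_name)

    def is_subset_of(self, other: "BinaryMask") -> bool:
        self.require_same_grid(other, "masks")
        return bool(np.all(other.data[self.as_bool()] == 1))


def read_volume(path: str | os.PathLike, units: str = "",
                as_mask: bool = False, region_name: str = "") -> Volume3D:
    """Read a NIfTI-1 volume.

    NIfTI carries no trustworthy unit field, so the caller supplies the
    unit label.  ``as_mask=True`` validates {0,1} content and returns a
    :class:`BinaryMask`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    n_bad = int(np.count_nonzero(~np.isfinite(data)))
    if n_bad:
        raise ValueError(f"{path}: {n_bad} NaN/Inf voxel(s) in input image")
    affine = np.asarray(img.affine, dtype=float)
    if as_mask:
        return BinaryMask(np.rint(data).astype(np.uint8), affine, "mask",
                          region_name=region_name)
    return Volume3D(data.astype(np.float32), affine, units)


def write_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz): float32 for scalars,
    uint8 for masks; the affine is stored at the header's float32
    precision (a NIfTI-1 format limit)."""
    parent = os.path.dirname(os.path.abspath(os.fspath(path)))
    if not os.path.isdir(parent) or not os.access(parent, os.W_OK):
        raise IOError(f"cannot write to {parent!r}")
    dtype = np.uint8 if isinstance(vol, BinaryMask) else np.float32
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.affine)
    img.header.set_data_dtype(dtype)
    nib.save(img, os.fspath(path))


def resample_to_grid(vol: Volume3D, target_spacing, interpolation: str = "trilinear") -> Volume3D:
    """Resample onto a grid with the given spacing covering the same
    world-space bounding box.

    Masks must use ``nearest`` to stay binary; requesting trilinear for a
    :class:`BinaryMask` is a contract error.  The output grid keeps the
    input's orientation (rotation part of the affine, renormalised to the
    new spacing) and origin, so any feature's world position moves by less
    than one target voxel.
    """
    target_spacing = np.asarray(target_spacing, dtype=float)
    if target_spacing.shape != (3,) or np.any(target_spacing <= 0):
        raise ValueError("target spacing must be three positive numbers")
    is_mask = isinstance(vol, BinaryMask)
    if interpolation not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if is_mask and interpolation != "nearest":
        raise ValueError("binary masks must be resampled with nearest-neighbour")

    scale = target_spacing / vol.spacing          # old voxels per new voxel
    new_shape = np.maximum(1, np.ceil(np.asarray(vol.shape) / scale - 1e-9)).astype(int)
    if np.allclose(scale, 1.0):
        new_shape = np.asarray(vol.shape)
    # new index j maps to old index j*scale; world affine scales accordingly
    S = np.diag([scale[0], scale[1], scale[2], 1.0])
    new_affine = vol.affine @ S

    if np.allclose(scale, 1.0):
        data = vol.data.copy()
    else:
        coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(new_shape, scale)],
                             indexing="ij")
        order = 0 if interpolation == "nearest" else 1
        data = ndimage.map_coordinates(
            vol.data.astype(np.float32 if not is_mask else np.uint8),
            np.stack(coords), order=order, mode="nearest")
    if is_mask:
        return BinaryMask(np.rint(data).astype(np.uint8), new_affine, "mask",
                          region_name=vol.region_name)
    return Volume3D(data.astype(np.float32), new_affine, vol.units)


def voi_mean(vol: Volume3D, mask: BinaryMask) -> tuple[float, int]:
    """Arithmetic mean of ``vol`` over ``mask==1`` voxels.

    Returns ``(mean, voxel_count)``.  An empty mask is an error (never a
    silent NaN); a grid mismatch is an alignment error.
    """
    vol.require_same_grid(mask, "volume and mask")
    m = mask.as_bool()
    n = int(m.sum())
    if n == 0:
        raise ValueError(f"empty mask {mask.region_name!r}: VOI mean undefined")
    return float(vol.data[m].mean(dtype=np.float64)), n
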