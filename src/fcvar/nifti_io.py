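"""Volumetric image IO and voxel bookkeeping.

All downstream computation works on masked time x voxel matrices; this module
owns the mapping between those matrices and NIfTI-1 volumes on disk.  Grids
must match exactly between images and masks -- the package never resamples,
since resampling choices would silently change every statistic computed on
the voxel values.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "Mask",
    "TimeSeriesMatrix",
    "GridMismatchError",
    "DataIntegrityError",
    "load_mask",
    "load_volume4d",
    "write_stat_map",
]

#: tolerance for affine / voxel-size agreement between grids
GRID_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Raised when an image does not live on the expected voxel grid."""


class DataIntegrityError(ValueError):
    """Raised when in-mask data contain non-finite values."""


@dataclasses.dataclass(frozen=True)
class VoxelGrid:
    """A 3D sampling grid: array shape, voxel size in mm and voxel-to-world affine."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be positive, got {vs}")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine must be invertible")
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @classmethod
    def from_img(cls, img: nib.spatialimages.SpatialImage) -> "VoxelGrid":
        shape = tuple(int(s) for s in img.shape[:3])
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(shape=shape, voxel_size=zooms, affine=np.asarray(img.affine, dtype=float))

    def matches(self, other: "VoxelGrid", atol: float = GRID_ATOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.affine, other.affine, atol=atol)
        )

    def require_match(self, other: "VoxelGrid", what: str = "image") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"incompatible grids: {what} has shape={other.shape}, "
                f"voxel_size={other.voxel_size}, affine=\n{other.affine}\n"
                f"expected shape={self.shape}, voxel_size={self.voxel_size}, "
                f"affine=\n{self.affine}"
            )


@dataclasses.dataclass(frozen=True)
class Mask:
    """An ordered set of in-grid voxel coordinates defining an analysis domain.

    Ordering is lexicographic by (i, j, k), i.e. C order of the nonzero voxels,
    and is a pure function of the coordinates -- stable across calls and
    platforms.  Every per-voxel vector in the package follows this ordering.
    """

    grid: VoxelGrid
    indices: np.ndarray  # (n_voxels, 3) int array, lexicographically sorted

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 2 or idx.shape[1] != 3:
            raise ValueError("indices must be an (n, 3) array")
        if idx.shape[0] < 1:
            raise ValueError("mask is empty")
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
        idx = idx[order]
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.grid.shape)):
            raise ValueError("mask indices out of grid bounds")
        if idx.shape[0] > 1 and np.any(np.all(np.diff(idx, axis=0) == 0, axis=1)):
            raise ValueError("mask indices are not unique")
        idx.setflags(write=False)
        object.__setattr__(self, "indices", idx)

    @property
    def n_voxels(self) -> int:
        return int(self.indices.shape[0])

    @classmethod
    def from_array(cls, arr: np.ndarray, grid: VoxelGrid) -> "Mask":
        arr = np.asarray(arr)
        if arr.shape != grid.shape:
            raise GridMismatchError(
                f"mask array shape {arr.shape} does not match grid shape {grid.shape}"
            )
        idx = np.argwhere(arr != 0)
        if idx.shape[0] == 0:
            raise ValueError("mask has no nonzero voxels")
        return cls(grid=grid, indices=idx)

    def to_array(self, dtype=bool) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=dtype)
        out[tuple(self.indices.T)] = 1
        return out

    def flat_index(self) -> np.ndarray:
        """C-order raveled positions of the mask voxels (ascending)."""
        return np.ravel_multi_index(tuple(self.indices.T), self.grid.shape)

    def values_to_volume(self, values: np.ndarray, background: float = 0.0) -> np.ndarray:
        values = np.asarray(values)
        if values.shape[0] != self.n_voxels:
            raise ValueError(
                f"expected {self.n_voxels} values, got {values.shape[0]}"
            )
        vol = np.full(self.grid.shape, background, dtype=float)
        vol[tuple(self.indices.T)] = values
        return vol


@dataclasses.dataclass
class TimeSeriesMatrix:
    """One run's masked BOLD data as a time x voxel matrix.

    Column order follows ``mask`` ordering; ``tr`` is the repetition time in
    seconds.
    """

    grid: VoxelGrid
    mask: Mask
    data: np.ndarray  # (n_volumes, n_voxels) float64
    tr: float
    run_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (time x voxel)")
        if self.data.shape[1] != self.mask.n_voxels:
            raise ValueError(
                f"data has {self.data.shape[1]} columns but mask has "
                f"{self.mask.n_voxels} voxels"
            )
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.data)):
            raise DataIntegrityError(f"non-finite values in run {self.run_id!r}")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[0])


def load_mask(path: str | Path, reference: VoxelGrid) -> Mask:
    """Read a binary 3D NIfTI mask, requiring an exact grid match (no resampling)."""
    img = nib.load(str(path))
    grid = VoxelGrid.from_img(img)
    reference.require_match(grid, what=str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 4 and arr.shape[3] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask image, got shape {arr.shape}")
    return Mask.from_array(arr != 0, reference)


def load_volume4d(
    path: str | Path,
    mask: Mask,
    tr: float,
    discard_initial: int = 0,
    run_id: str | None = None,
) -> TimeSeriesMatrix:
    """Read a 4D NIfTI run restricted to ``mask``, dropping the first
    ``discard_initial`` volumes (signal-equilibration frames)."""
    img = nib.load(str(path))
    if len(img.shape) != 4:
        raise ValueError(f"{path}: expected a 4D image, got shape {img.shape}")
    grid = VoxelGrid.from_img(img)
    mask.grid.require_match(grid, what=str(path))
    n_vol = img.shape[3]
    if discard_initial < 0 or discard_initial >= n_vol:
        raise ValueError(
            f"discard_initial={discard_initial} out of range for {n_vol} volumes"
        )
    arr = np.asanyarray(img.dataobj)
    data = arr[tuple(mask.indices.T)].T.astype(np.float64)  # (time, voxel)
    data = data[discard_initial:]
    if not np.all(np.isfinite(data)):
        raise DataIntegrityError(f"{path}: non-finite voxel values inside mask")
    return TimeSeriesMatrix(
        grid=mask.grid,
        mask=mask,
        data=data,
        tr=float(tr),
        run_id=run_id if run_id is not None else Path(path).name,
    )


def write_stat_map(
    values: Sequence[float] | np.ndarray,
    mask: Mask,
    path: str | Path,
    background: float = 0.0,
) -> None:
    """Write per-voxel values as a float32 3D NIfTI on the mask's grid.

    Out-of-mask voxels carry ``background`` (use 1.0 for p-value maps so that
    thresholding tools never see fake significance outside the mask).
    """
    vol = mask.values_to_volume(np.asarray(values, dtype=np.float64), background)
    img = nib.Nifti1Image(vol.astype(np.float32), mask.grid.affine)
    img.header.set_zooms(mask.grid.voxel_size)
    nib.save(img, str(path))
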