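"""NIfTI-1 I/O, voxel grids, masks, and mask resampling.

All voxel bookkeeping in the pipeline uses one fixed linear voxel order:
lexicographic over array indices with the first (x) axis fastest, i.e.
``linear = i + nx*(j + ny*k)`` for voxel ``(i, j, k)`` on an ``(nx, ny, nz)``
grid.  This is NumPy's Fortran ravel order and matches the on-disk layout of
NIfTI-1, so time-series columns map to voxels reproducibly across runs.

Voxel indices are 0-based; affines follow the NIfTI world-coordinate
convention (voxel index -> mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    DegenerateInputError,
    DimensionalityError,
    FormatError,
    GridMismatchError,
    ManifestError,
)

#: absolute tolerance (mm) on affine entries when deciding grid compatibility
AFFINE_ATOL = 1e-4

GROUPS = ("nonautistic", "autistic")
CONDITIONS = ("placebo", "drug")

MANIFEST_COLUMNS = ["participant_id", "group", "condition", "bold_path", "fd_path", "mfd"]


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice: shape plus the voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise DimensionalityError(f"grid shape must be 3 positive ints, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise DimensionalityError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def compatible_with(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=AFFINE_ATOL, rtol=0.0
        )

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to (fractional) voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


def linear_order_indices(shape: tuple[int, int, int], membership: np.ndarray) -> np.ndarray:
    """Linear (x-fastest) indices of the true voxels of ``membership``."""
    return np.flatnonzero(np.ravel(membership, order="F"))


@dataclass
class MaskVolume:
    """Boolean voxel membership on a grid."""

    grid: VoxelGrid
    membership: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        memb = np.asarray(self.membership)
        if memb.shape != self.grid.shape:
            raise DimensionalityError(
                f"membership shape {memb.shape} != grid shape {self.grid.shape}"
            )
        self.membership = memb.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())

    def linear_indices(self) -> np.ndarray:
        """In-mask voxel positions in the fixed linear (x-fastest) order."""
        return linear_order_indices(self.grid.shape, self.membership)

    def intersect(self, other: "MaskVolume", label: str | None = None) -> "MaskVolume":
        if not self.grid.compatible_with(other.grid):
            raise GridMismatchError("cannot intersect masks on incompatible grids")
        return MaskVolume(
            self.grid,
            self.membership & other.membership,
            label if label is not None else f"{self.label}&{other.label}",
        )

    def is_subset_of(self, other: "MaskVolume") -> bool:
        return bool(np.all(~self.membership | other.membership))


@dataclass
class BoldSession:
    """One participant-condition acquisition restricted to an analysis mask.

    ``timeseries`` is T x N with column j the j-th in-mask voxel in the fixed
    linear order of the mask.
    """

    participant_id: str
    group: str
    condition: str
    grid: VoxelGrid
    timeseries: np.ndarray
    mask: MaskVolume = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ManifestError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.condition not in CONDITIONS:
            raise ManifestError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2:
            raise DimensionalityError("timeseries must be 2D (T x N)")
        if not np.all(np.isfinite(ts)):
            raise DegenerateInputError("timeseries contains non-finite values")
        if self.mask is not None and ts.shape[1] != self.mask.n_voxels:
            raise DimensionalityError(
                f"timeseries has {ts.shape[1]} columns but mask has {self.mask.n_voxels} voxels"
            )
        self.timeseries = ts

    @property
    def n_timepoints(self) -> int:
        return int(self.timeseries.shape[0])


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> tuple[VoxelGrid, np.ndarray]:
    """Read a 3D or 4D NIfTI-1 volume.

    Returns the voxel grid (of the spatial axes) and the data array; for 4D
    data the last axis is time.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    if data.ndim not in (3, 4):
        raise DimensionalityError(f"{path}: expected 3D or 4D image, got {data.ndim}D")
    grid = VoxelGrid(tuple(data.shape[:3]), np.asarray(img.affine, dtype=float))
    return grid, np.asarray(data, dtype=float)


def write_volume(path: str | Path, grid: VoxelGrid, data: np.ndarray) -> None:
    """Write a 3D or 4D array to NIfTI-1."""
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise DimensionalityError(f"expected 3D or 4D array, got {data.ndim}D")
    if tuple(data.shape[:3]) != grid.shape:
        raise DimensionalityError("data spatial shape does not match grid")
    img = nib.Nifti1Image(data, grid.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path, label: str = "") -> MaskVolume:
    grid, data = read_volume(path)
    if data.ndim != 3:
        raise DimensionalityError("mask file must be 3D")
    return MaskVolume(grid, data > 0.5, label or Path(path).stem)


def write_mask(path: str | Path, mask: MaskVolume) -> None:
    write_volume(path, mask.grid, mask.membership.astype(np.uint8))


# ---------------------------------------------------------------------------
# Time-series extraction
# ---------------------------------------------------------------------------

def extract_timeseries(grid: VoxelGrid, bold_4d: np.ndarray, mask: MaskVolume) -> np.ndarray:
    """Extract the T x N in-mask time-series matrix from a 4D BOLD array.

    Column order is the fixed linear voxel order of the mask and depends on
    geometry only, never on labels.
    """
    bold_4d = np.asarray(bold_4d, dtype=float)
    if bold_4d.ndim != 4:
        raise DimensionalityError("bold data must be 4D")
    if tuple(bold_4d.shape[:3]) != grid.shape:
        raise DimensionalityError("bold spatial shape does not match its grid")
    if not grid.compatible_with(mask.grid):
        raise GridMismatchError("bold grid and mask grid are not compatible")
    if mask.n_voxels == 0:
        raise DegenerateInputError("mask is empty")
    n_xyz = grid.n_voxels
    t = bold_4d.shape[3]
    # F-order reshape maps voxel (i,j,k) to row i + nx*(j + ny*k), time to column
    flat = bold_4d.reshape((n_xyz, t), order="F")
    return flat[mask.linear_indices(), :].T


# ---------------------------------------------------------------------------
# Mask resampling
# ---------------------------------------------------------------------------

def resample_mask_nearest(mask: MaskVolume, target: VoxelGrid) -> MaskVolume:
    """Resample a mask onto ``target`` by nearest neighbour in world space.

    Resampling onto the mask's own grid is the identity.  Output is strictly
    boolean; target voxels whose nearest source voxel lies outside the source
    field of view are false.
    """
    return resample_mask(mask, target, interpolation="nearest")


def resample_mask(
    mask: MaskVolume, target: VoxelGrid, interpolation: str = "nearest"
) -> MaskVolume:
    """Resample a mask onto a target grid.

    ``interpolation`` is ``"nearest"`` (default) or ``"linear"``; after linear
    interpolation membership is binarized as value > 0.5.
    """
    if mask.grid.compatible_with(target):
        return MaskVolume(target, mask.membership.copy(), mask.label)
    tgt_idx = np.indices(target.shape).reshape(3, -1).T  # (n, 3) voxel indices
    world = target.voxel_to_world(tgt_idx)
    src = mask.grid.world_to_voxel(world)  # fractional source voxel coords
    if interpolation == "nearest":
        near = np.rint(src).astype(np.int64)
        inside = np.all((near >= 0) & (near < np.array(mask.grid.shape)), axis=1)
        out = np.zeros(len(tgt_idx), dtype=bool)
        ii = near[inside]
        out[inside] = mask.membership[ii[:, 0], ii[:, 1], ii[:, 2]]
    elif interpolation == "linear":
        vals = ndimage.map_coordinates(
            mask.membership.astype(np.float64), src.T, order=1, mode="constant", cval=0.0
        )
        out = vals > 0.5
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return MaskVolume(target, out.reshape(target.shape), mask.label)


# ---------------------------------------------------------------------------
# Session manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the TSV session manifest and validate its contents."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    except Exception as exc:
        raise FormatError(f"cannot read manifest {path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise ManifestError(f"unknown group labels: {sorted(bad_group)}")
    bad_cond = set(df["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ManifestError(f"unknown condition labels: {sorted(bad_cond)}")
    dup = df.duplicated(subset=["participant_id", "condition"])
    if dup.any():
        raise ManifestError(
            f"duplicate participant x condition rows: {df.loc[dup, 'participant_id'].tolist()}"
        )
    return df


def write_manifest(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, columns=MANIFEST_COLUMNS)
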