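"""Volume and covariate I/O, analysis masks, and voxel-by-subject response matrices.

All statistics in this package operate in 0-based voxel index space; the NIfTI
affine is carried through I/O for provenance but never used in computation.
Stored mask values are binarised at 0.5 (interpolation after spatial
normalisation leaves near-binary residue; values materially outside [0, 1]
are rejected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelGrid",
    "BinaryLesionVolume",
    "ResponseMatrix",
    "load_mask_stack",
    "write_volume",
    "binarise",
    "build_response_matrix",
    "incidence_map",
    "stack_to_array",
    "load_covariates",
]

_BINARY_TOL = 1e-6


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid shared by every volume in a study.

    Attributes
    ----------
    shape : tuple of int
        ``(nx, ny, nz)``, each >= 1.
    voxel_size : float
        Physical voxel edge length in mm (> 0); informational only.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform; carried, never used for statistics.
    """

    shape: tuple[int, ...]
    voxel_size: float = 2.0
    affine: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise ValueError(f"grid shape must be three positive integers, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be > 0")
        affine = self.affine
        if affine is None:
            affine = np.diag([self.voxel_size] * 3 + [1.0])
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        affine.setflags(write=False)
        object.__setattr__(self, "affine", affine)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def compatible(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclass
class BinaryLesionVolume:
    """One subject's 3D lesion presence/absence map."""

    grid: VoxelGrid
    data: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        uniq = np.unique(data)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("lesion volume values must be exactly 0 or 1")
        self.data = data.astype(np.uint8)


@dataclass
class ResponseMatrix:
    """Binary responses for the active (non-zero incidence) voxels.

    ``values`` is voxel-major, shape ``(M_active, N)``; row ``r`` corresponds
    to voxel coordinate ``voxel_index[r]`` (0-based ``(i, j, k)``).
    """

    values: np.ndarray
    voxel_index: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.uint8)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (voxels x subjects)")
        if self.voxel_index.shape != (self.values.shape[0], 3):
            raise ValueError("voxel_index must be (M_active, 3)")

    @property
    def n_active(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    def incidence(self) -> np.ndarray:
        """Per-active-voxel lesion incidence, shape (M_active,)."""
        return self.values.mean(axis=1)

    def scatter(self, row_values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place per-row values back into a 3D volume."""
        vol = np.full(self.grid.shape, fill, dtype=float)
        vol[tuple(self.voxel_index.T)] = row_values
        return vol


def binarise(data: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarise near-binary values at ``threshold`` (>= threshold -> 1).

    Values outside [0, 1] beyond a small tolerance raise, as they indicate a
    volume that is not a (possibly interpolated) mask.
    """
    data = np.asarray(data, dtype=float)
    if np.nanmin(data) < -_BINARY_TOL or np.nanmax(data) > 1 + _BINARY_TOL:
        raise ValueError(
            f"values outside [0, 1] (range {np.nanmin(data):g}..{np.nanmax(data):g}); "
            "not a binary mask"
        )
    return (data >= threshold).astype(np.uint8)


def load_mask_stack(paths: Sequence) -> tuple[list[BinaryLesionVolume], VoxelGrid]:
    """Read a stack of binary lesion volumes sharing one grid.

    Near-binary values (interpolation residue) are binarised at 0.5. A grid
    mismatch or genuinely non-binary volume raises, naming the file.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("no volume paths given")
    stack: list[BinaryLesionVolume] = []
    grid: VoxelGrid | None = None
    for path in paths:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
        zooms = img.header.get_zooms()[:3]
        this_grid = VoxelGrid(shape=data.shape, voxel_size=float(zooms[0]), affine=img.affine)
        if grid is None:
            grid = this_grid
        elif not grid.compatible(this_grid):
            raise ValueError(f"{path}: grid mismatch (shape {data.shape} vs {grid.shape})")
        try:
            binary = binarise(data)
        except ValueError as err:
            raise ValueError(f"{path}: {err}") from err
        stack.append(BinaryLesionVolume(grid=grid, data=binary, subject_id=Path(path).stem))
    assert grid is not None
    return stack, grid


def write_volume(path, data: np.ndarray, grid: VoxelGrid) -> None:
    """Write a 3D volume as NIfTI; float maps at 32-bit, masks as uint8."""
    data = np.asarray(data)
    if data.shape != grid.shape:
        raise ValueError("data shape does not match grid")
    dtype = np.uint8 if data.dtype == np.uint8 else np.float32
    img = nib.Nifti1Image(data.astype(dtype), np.asarray(grid.affine))
    img.header.set_zooms((grid.voxel_size,) * 3)
    nib.save(img, str(path))


def stack_to_array(stack: Sequence[BinaryLesionVolume]) -> np.ndarray:
    """Stack volumes into an ``(N, nx, ny, nz)`` uint8 array."""
    if not stack:
        raise ValueError("empty stack")
    grid = stack[0].grid
    for vol in stack[1:]:
        if not grid.compatible(vol.grid):
            raise ValueError("stack volumes are on different grids")
    return np.stack([vol.data for vol in stack])


def build_response_matrix(
    stack: Sequence[BinaryLesionVolume], brain_mask: np.ndarray | None = None
) -> ResponseMatrix:
    """Collect responses for voxels with non-zero lesion incidence.

    Determines the active voxels (inside ``brain_mask`` if given, with at
    least one lesion across subjects) first and keeps binary values only for
    those, voxel-major, which is what the voxel-wise fitters stream.
    """
    arr = stack_to_array(stack)
    grid = stack[0].grid
    any_lesion = arr.any(axis=0)
    if brain_mask is not None:
        brain_mask = np.asarray(brain_mask).astype(bool)
        if brain_mask.shape != grid.shape:
            raise ValueError("brain_mask shape does not match grid")
        any_lesion &= brain_mask
    idx = np.argwhere(any_lesion)
    if idx.shape[0] == 0:
        logger.warning("no voxels with non-zero lesion incidence; empty response matrix")
        return ResponseMatrix(
            values=np.empty((0, len(stack)), dtype=np.uint8),
            voxel_index=np.empty((0, 3), dtype=np.intp),
            grid=grid,
        )
    values = arr[:, idx[:, 0], idx[:, 1], idx[:, 2]].T
    return ResponseMatrix(values=values, voxel_index=idx, grid=grid)


def incidence_map(stack: Sequence[BinaryLesionVolume]) -> np.ndarray:
    """Per-voxel fraction of subjects with a lesion, shape = grid shape."""
    arr = stack_to_array(stack)
    return arr.mean(axis=0)


def load_covariates(path, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a delimited covariate table (CSV/TSV by extension) with a header."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep)
    if columns is not None:
        missing = [c for c in columns if c not in table.columns]
        if missing:
            raise KeyError(f"covariate columns not found: {missing}")
        table = table[list(columns)]
    return table
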