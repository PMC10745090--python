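"""Voxel grids and per-voxel scalar maps.

A :class:`VoxelGrid` is the spatial scaffold shared by every map in an
analysis: one row per voxel with millimetre coordinates and a hemisphere
label.  Voxels must sit on a regular lattice (a subset of a box is fine —
real brain masks are irregular), which is what makes Gaussian smoothing
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class GridError(ValueError):
    """Voxel set is not a regular grid, or two grids do not match."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice with hemisphere labels.

    Parameters
    ----------
    coords : (n, 3) float array
        Voxel centre coordinates in mm.
    hemisphere : (n,) array of {"L", "R"}
    voxel_ids : (n,) int array
        Stable voxel identifiers (default 0..n-1).
    """

    coords: np.ndarray
    hemisphere: np.ndarray
    voxel_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GridError("coords must be an (n, 3) array of mm positions")
        object.__setattr__(self, "coords", coords)
        hemi = np.asarray(self.hemisphere)
        if hemi.shape[0] != coords.shape[0]:
            raise GridError("hemisphere labels must match voxel count")
        object.__setattr__(self, "hemisphere", hemi)
        if self.voxel_ids is None:
            object.__setattr__(self, "voxel_ids", np.arange(coords.shape[0]))
        else:
            ids = np.asarray(self.voxel_ids, dtype=int)
            if ids.shape[0] != coords.shape[0]:
                raise GridError("voxel_ids must match voxel count")
            object.__setattr__(self, "voxel_ids", ids)

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    def lattice_indices(self, voxel_size_mm) -> tuple[np.ndarray, tuple[int, int, int]]:
        """Integer (i, j, k) lattice indices of each voxel.

        Raises :class:`GridError` if any coordinate is off-lattice for the
        given spacing.
        """
        size = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
        rel = (self.coords - self.coords.min(axis=0)) / size
        idx = np.round(rel).astype(int)
        if not np.allclose(rel, idx, atol=1e-6):
            raise GridError("voxel coordinates are not on a regular grid "
                            f"with spacing {size}")
        shape = tuple(int(m) + 1 for m in idx.max(axis=0))
        flat = np.ravel_multi_index(tuple(idx.T), shape)
        if len(np.unique(flat)) != self.n_voxels:
            raise GridError("duplicate voxel positions on the lattice")
        return idx, shape

    def same_as(self, other: "VoxelGrid") -> bool:
        return (self.n_voxels == other.n_voxels
                and np.array_equal(self.voxel_ids, other.voxel_ids)
                and np.allclose(self.coords, other.coords))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "voxel_id": self.voxel_ids,
            "x_mm": self.coords[:, 0],
            "y_mm": self.coords[:, 1],
            "z_mm": self.coords[:, 2],
            "hemisphere": self.hemisphere,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VoxelGrid":
        return cls(
            coords=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
            hemisphere=df["hemisphere"].to_numpy(),
            voxel_ids=df["voxel_id"].to_numpy(int),
        )


@dataclass
class VoxelMap:
    """Per-voxel scalar field (R, ΔR, t, z, p, specificity ...) on a grid."""

    values: np.ndarray
    grid: VoxelGrid
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_voxels,):
            raise GridError("map length does not match grid voxel count")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise GridError("valid mask length does not match map")

    def to_frame(self, column: str = "value") -> pd.DataFrame:
        return pd.DataFrame({"voxel_id": self.grid.voxel_ids, column: self.values})


def check_same_grid(a: VoxelGrid, b: VoxelGrid) -> None:
    if not a.same_as(b):
        raise GridError("voxel grids do not match")
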