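"""Voxel grid geometry for dose fields and structure masks.

All volumes in the package live on isotropic voxel grids. Voxel indices are
0-based; a voxel's world coordinate is the coordinate of its *center*,
``world = origin_mm + index * spacing_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "DoseGrid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an isotropic 3D voxel grid.

    Parameters
    ----------
    shape
        Voxel counts per axis, each >= 1.
    spacing_mm
        Isotropic voxel edge length in millimetres (default 1.0).
    origin_mm
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing_mm: float = 1.0
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        origin = tuple(float(x) for x in self.origin_mm)
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if len(origin) != 3:
            raise ValueError("origin_mm must have three components")
        if not self.spacing_mm > 0:
            raise ValueError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", float(self.spacing_mm))
        object.__setattr__(self, "origin_mm", origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres."""
        return self.spacing_mm**3 / 1000.0

    @property
    def center_mm(self) -> np.ndarray:
        """World coordinate of the geometric center of the grid."""
        return np.asarray(self.origin_mm) + (np.asarray(self.shape) - 1) / 2.0 * self.spacing_mm

    def contains_index(self, index) -> bool:
        idx = np.asarray(index)
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.shape)))

    def index_to_world(self, index) -> np.ndarray:
        return np.asarray(self.origin_mm) + np.asarray(index, dtype=float) * self.spacing_mm

    def world_to_index(self, world) -> np.ndarray:
        """Nearest voxel index for a world coordinate (may lie outside the grid)."""
        cont = (np.asarray(world, dtype=float) - np.asarray(self.origin_mm)) / self.spacing_mm
        return np.rint(cont).astype(int)

    def volume_cc(self, mask: np.ndarray) -> float:
        """Volume of a binary mask on this grid, in cc."""
        if mask.shape != self.shape:
            raise ValueError(f"mask shape {mask.shape} does not match grid {self.shape}")
        return float(np.count_nonzero(mask)) * self.voxel_volume_cc


@dataclass
class DoseGrid:
    """A non-negative scalar dose field on a :class:`GridSpec`.

    Dose values are relative (the planning chain normalises to the 50%
    isodose line), so no absolute unit is attached.
    """

    values: np.ndarray
    grid: GridSpec = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.values.size and float(self.values.min()) < 0:
            raise ValueError("dose values must be non-negative")

    @property
    def max(self) -> float:
        return float(self.values.max())

    @classmethod
    def zeros(cls, grid: GridSpec) -> "DoseGrid":
        return cls(np.zeros(grid.shape, dtype=np.float32), grid)
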