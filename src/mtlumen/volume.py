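"""Density volumes: the raster form of synthetic or real tomogram data.

A :class:`DensityVolume` is a 3D intensity grid with a physical voxel size
(nm) and a world origin.  The grid is indexed ``grid[ix, iy, iz]`` and the
world position of a voxel centre is ``origin + (index + 0.5) * voxel_size``
(0-based indices, origin at the corner of voxel (0, 0, 0)), so that
continuous nm coordinates and voxel indices round-trip unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DensityVolume"]


@dataclass
class DensityVolume:
    grid: np.ndarray                 # (nx, ny, nz) float32
    voxel_size: float                # nm
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))  # nm

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3D")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid intensities must be finite")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    def index_to_position(self, idx: np.ndarray) -> np.ndarray:
        """World position (nm) of voxel centre(s) for (possibly fractional) indices."""
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.voxel_size

    def position_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Fractional voxel index of world position(s) in nm."""
        return (np.asarray(pos, dtype=float) - self.origin) / self.voxel_size - 0.5

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis (nm)."""
        n = self.grid.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.grid.copy(), self.voxel_size, self.origin.copy())
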