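"""Voxel-grid geometry shared by masks, graphs and maps.

All analysis stages operate on a common template grid: a regular 3-D lattice
with an isotropic-or-not voxel size in millimetres and an origin offset, so
that voxel index ``(i, j, k)`` maps to ``index * voxel_size + origin`` in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """Raised for invalid grid geometry (non-positive voxel sizes, bad shapes)."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis; every entry must be >= 1.
    voxel_size
        Edge length of one voxel in mm per axis; every entry must be > 0.
    origin
        World-space (mm) position of the centre of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.voxel_size) != 3 or len(self.origin) != 3:
            raise GeometryError("shape, voxel_size and origin must be length-3")
        if any(int(s) < 1 or int(s) != s for s in self.shape):
            raise GeometryError(f"all shape entries must be integers >= 1, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise GeometryError(f"all voxel sizes must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def index_to_mm(self, index) -> np.ndarray:
        """Map voxel indices (…, 3) to world coordinates in mm."""
        idx = np.asarray(index, dtype=float)
        return idx * np.asarray(self.voxel_size) + np.asarray(self.origin)

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-mm affine (diagonal scaling plus origin translation)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    def brain_mask(self) -> np.ndarray:
        """Axis-aligned ellipsoid inscribed in the grid, as a boolean array.

        Stands in for an anatomical brain mask: it bounds where lesions and
        substrates may live and what counts as an in-brain node.
        """
        centre = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        semi = np.asarray(self.shape, dtype=float) / 2.0
        grids = np.meshgrid(*[np.arange(s, dtype=float) for s in self.shape], indexing="ij")
        d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
        return d2 <= 1.0


def make_grid(shape, voxel_size=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> GridSpec:
    """Construct a :class:`GridSpec`, validating geometry."""
    return GridSpec(tuple(shape), tuple(voxel_size), tuple(origin))
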