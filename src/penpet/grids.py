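"""Voxel grid description shared by the phantom builder, simulator and reconstruction.

The grid is a 2D multi-slice stack: square in-plane pixels of ``pixel_size`` mm
and independent axial slices of ``slice_thickness`` mm.  Coordinates are in mm
with the origin at the grid center, x along axis 0, y along axis 1, z along
axis 2 (slice direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Image grid: ``nx x ny`` pixels per slice, ``n_slices`` slices.

    The desk-scale default (128 x 128 at 2.5 mm, 19 slices of 2.78 mm) keeps
    reconstruction fast while preserving the slice-thickness-dependent ROI
    offsets of the NEMA protocol.  The clinical 256 x 256 matrix is supported
    by configuration.
    """

    nx: int = 128
    ny: int = 128
    n_slices: int = 19
    pixel_size: float = 2.5
    slice_thickness: float = 2.78

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0 or self.n_slices <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size <= 0 or self.slice_thickness <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.n_slices)

    @property
    def fov(self) -> float:
        """Transaxial field of view along x, mm."""
        return self.nx * self.pixel_size

    @property
    def central_slice(self) -> int:
        return (self.n_slices - 1) // 2

    @property
    def voxel_volume_ml(self) -> float:
        return self.pixel_size**2 * self.slice_thickness / 1000.0

    def xs(self) -> np.ndarray:
        """Pixel-center x coordinates (mm), centered on the grid."""
        return (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.pixel_size

    def ys(self) -> np.ndarray:
        return (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.pixel_size

    def zs(self) -> np.ndarray:
        """Slice-center z coordinates (mm), zero at the central slice."""
        return (np.arange(self.n_slices) - self.central_slice) * self.slice_thickness

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane coordinate arrays of shape (nx, ny)."""
        return np.meshgrid(self.xs(), self.ys(), indexing="ij")

    def affine(self) -> np.ndarray:
        """NIfTI affine mapping voxel indices to mm coordinates."""
        aff = np.diag([self.pixel_size, self.pixel_size, self.slice_thickness, 1.0])
        aff[0, 3] = self.xs()[0]
        aff[1, 3] = self.ys()[0]
        aff[2, 3] = self.zs()[0]
        return aff
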