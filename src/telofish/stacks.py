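"""Core image containers: voxel geometry and 3D channel stacks.

Conventions used throughout the package:

* Axis order is ``(z, y, x)`` with 0-based indices.
* Physical coordinates are reported in nanometres from the stack origin;
  the centre of voxel ``(iz, iy, ix)`` sits at
  ``(iz * dz_nm, iy * dy_nm, ix * dx_nm)``.
* Intensities are photon counts and are never negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelSize", "ImageStack"]


@dataclass(frozen=True)
class VoxelSize:
    """Physical voxel spacing in nanometres.

    Defaults correspond to confocal acquisition at 80 nm lateral and
    200 nm axial sampling.
    """

    dx_nm: float = 80.0
    dy_nm: float = 80.0
    dz_nm: float = 200.0

    def __post_init__(self) -> None:
        for name in ("dx_nm", "dy_nm", "dz_nm"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"VoxelSize.{name} must be strictly positive, got {v!r}")

    @property
    def zyx_nm(self) -> tuple[float, float, float]:
        """Spacing in (z, y, x) order, matching array axes."""
        return (self.dz_nm, self.dy_nm, self.dx_nm)

    def voxel_volume_nm3(self) -> float:
        return self.dx_nm * self.dy_nm * self.dz_nm


@dataclass
class ImageStack:
    """A single-channel 3D image with physical voxel sizes.

    Parameters
    ----------
    voxels
        3D array indexed ``(z, y, x)``; nonnegative photon counts.
    voxel_size
        Physical spacing of the grid.
    channel_name
        Label for the channel, conventionally ``"dapi"`` or ``"telomere"``.
    """

    voxels: np.ndarray
    voxel_size: VoxelSize = field(default_factory=VoxelSize)
    channel_name: str = "telomere"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got ndim={self.voxels.ndim}")
        if any(s == 0 for s in self.voxels.shape):
            raise ValueError(f"stack shape must be nonzero in all axes, got {self.voxels.shape}")
        if np.any(self.voxels < 0):
            raise ValueError("negative intensities are not allowed (values are photon counts)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def coordinate_nm(self, index_zyx: tuple[float, float, float]) -> tuple[float, float, float]:
        """Physical (z, y, x) position in nm of a (possibly fractional) index."""
        dz, dy, dx = self.voxel_size.zyx_nm
        iz, iy, ix = index_zyx
        return (iz * dz, iy * dy, ix * dx)

    def index_of_nm(self, pos_zyx_nm: tuple[float, float, float]) -> tuple[float, float, float]:
        """Fractional (z, y, x) index of a physical position in nm."""
        dz, dy, dx = self.voxel_size.zyx_nm
        z, y, x = pos_zyx_nm
        return (z / dz, y / dy, x / dx)

    def copy_with(self, voxels: np.ndarray) -> "ImageStack":
        return ImageStack(voxels=voxels, voxel_size=self.voxel_size, channel_name=self.channel_name)
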