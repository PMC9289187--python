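"""The unit of image data: a single-channel 3D intensity volume.

Arrays are ordered ``(z, y, x)``, 0-based, with voxel centers at
``(i + 0.5) * voxel_size`` along each axis. All physical quantities are in
micrometres; voxel sizes are anisotropic (confocal Z sampling is coarser
than XY).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoxelGrid:
    """A 3D scalar intensity volume with physical voxel dimensions.

    Parameters
    ----------
    data
        Intensity array of shape ``(nz, ny, nx)``; non-negative.
    voxel_size
        Physical voxel extent ``(dz, dy, dx)`` in µm.
    channel_name
        Fluorescence channel this volume belongs to (e.g. ``"dapi"``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be three positive floats, got {self.voxel_size}")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def physical_extent(self) -> tuple[float, float, float]:
        """Physical size of the whole stack ``(z, y, x)`` in µm."""
        return tuple(s * v for s, v in zip(self.data.shape, self.voxel_size))

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """A copy of this grid carrying ``data`` with unchanged geometry."""
        return VoxelGrid(data=data, voxel_size=self.voxel_size, channel_name=self.channel_name)
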