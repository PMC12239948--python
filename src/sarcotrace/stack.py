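"""Multichannel 3D intensity stacks with physical voxel pitch.

A :class:`VoxelStack` is the raw input of the whole pipeline: a confocal
z-stack with one array per fluorescence channel, laid out ``[channel][z][y][x]``,
plus the physical voxel pitch in micrometers.  Coordinates throughout the
package are physical (μm), refer to voxel centers, and use 0-based voxel
indices internally: voxel ``(iz, iy, ix)`` sits at ``(ix*dx, iy*dy, iz*dz)``.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: canonical channel names used by the synthetic generator and the pipeline
CHANNELS = ("actin", "sls", "mhc", "obscurin")

#: default voxel pitch (dx, dy, dz) in μm for flight-muscle stacks:
#: 0.03321 μm lateral pixels and a 200 nm z-step
FLIGHT_PITCH = (0.03321, 0.03321, 0.2)

#: lateral pixel size used for larval-muscle images
LARVAL_PITCH = (0.06589, 0.06589, 0.2)


@dataclass
class VoxelStack:
    """Multichannel 3D intensity grid.

    Parameters
    ----------
    intensities
        Non-negative array of shape ``(n_channels, nz, ny, nx)``.
    pitch
        ``(dx, dy, dz)`` voxel pitch in μm; all components positive.
    channel_names
        Unique channel labels, one per leading-axis plane.
    """

    intensities: np.ndarray
    pitch: tuple[float, float, float]
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be a (channel, z, y, x) array")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        self.pitch = tuple(float(p) for p in self.pitch)
        if len(self.pitch) != 3 or any(p <= 0 for p in self.pitch):
            raise ValueError("pitch must be three positive components (dx, dy, dz)")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.intensities.shape[0]:
            raise ValueError("one channel name per channel plane required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    # -- accessors ---------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in stack {self.channel_names}") from None

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) intensity array of one channel."""
        return self.intensities[self.index(name)]

    def with_channel(self, name: str, data: np.ndarray) -> "VoxelStack":
        """Return a copy of the stack with one channel replaced."""
        if data.shape != self.shape_zyx:
            raise ValueError("replacement channel shape mismatch")
        new = self.intensities.copy()
        new[self.index(name)] = data
        return replace(self, intensities=new)

    def extent_um(self) -> tuple[float, float, float]:
        """Physical (x, y, z) extent in μm spanned by voxel centers."""
        nz, ny, nx = self.shape_zyx
        dx, dy, dz = self.pitch
        return ((nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz)
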