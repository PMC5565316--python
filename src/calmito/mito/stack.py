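"""Containers for TMRE stacks and ganglion masks.

All geometry is held in micrometres internally; voxel sizes are (z, y, x)
and may be anisotropic. Stacks are (T, Z, Y, X); a single time point is
stored with T = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MitoStack:
    """A 3D(+time) TMRE fluorescence stack.

    voxels: (T, Z, Y, X) float array, arbitrary units.
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be (T, Z, Y, X) or (Z, Y, X)")
        if min(self.voxels.shape) < 1:
            raise ValueError("all stack dimensions must be >= 1")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)  # type: ignore[assignment]
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be three positive (z, y, x) values")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack intensities must be finite")
        if self.voxels.shape[0] > 1 and self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive for a time series")

    @property
    def n_frames(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def voxel_volume_um3(self) -> float:
        vz, vy, vx = self.voxel_size_um
        return vz * vy * vx

    def frame(self, t: int) -> np.ndarray:
        return self.voxels[t]


@dataclass
class GanglionMask:
    """Binary 3D volume of interest drawn around the injected ganglion.

    Used as a mask for every detection step; its volume is the denominator
    of the mitochondrial density and volume-ratio statistics.
    """

    mask: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("ganglion mask must be 3-D (Z, Y, X)")
        if not self.mask.any():
            raise ValueError("ganglion mask is empty")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)  # type: ignore[assignment]
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be three positive (z, y, x) values")

    @property
    def voxel_volume_um3(self) -> float:
        vz, vy, vx = self.voxel_size_um
        return vz * vy * vx

    @property
    def volume_um3(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume_um3

    @classmethod
    def from_ellipsoid(
        cls,
        shape_zyx: tuple[int, int, int],
        voxel_size_um: tuple[float, float, float],
        center_um: tuple[float, float, float],
        radii_um: tuple[float, float, float],
    ) -> "GanglionMask":
        """Rasterize an ellipsoidal volume of interest (voxel-centre test)."""
        if any(r <= 0 for r in radii_um):
            raise ValueError("ellipsoid radii must be positive")
        grids = np.ogrid[: shape_zyx[0], : shape_zyx[1], : shape_zyx[2]]
        acc = np.zeros(shape_zyx)
        for g, v, c, r in zip(grids, voxel_size_um, center_um, radii_um):
            acc = acc + (((g + 0.5) * v - c) / r) ** 2
        return cls(acc <= 1.0, voxel_size_um)
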