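"""Volume and mask containers shared by every stage of the pipeline.

Conventions
-----------
* Arrays are indexed ``[x, y, z]`` with 0-based voxel indices; the axial
  (in-plane) plane is the ``x``/``y`` plane and ``z`` is the slice axis.
* ``spacing`` is millimetres per voxel along (x, y, z).  Distances are always
  measured in physical (world) millimetres; masks live on the exact grid of
  their parent volume and are never resampled.
* Intensities are Hounsfield units (HU): air ~ -1000, aerated lung ~ -850,
  soft tissue ~ 0-100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume", "VoxelMask", "SeedPoint", "GeometryError"]


class GeometryError(ValueError):
    """Raised when grids that must share geometry do not."""


@dataclass
class CTVolume:
    """A 3-D CT attenuation grid in Hounsfield units.

    Parameters
    ----------
    data:
        3-D float array of HU values, indexed ``[x, y, z]``.
    spacing:
        Voxel edge lengths in mm along (x, y, z).
    origin:
        World coordinate (mm) of voxel (0, 0, 0).
    orientation:
        Axis-direction codes; ``"RAS"`` by default.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("CT volume must be a non-empty 3-D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("HU values must be finite")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "CTVolume | VoxelMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def contains_index(self, idx: tuple[int, int, int]) -> bool:
        return all(0 <= i < n for i, n in zip(idx, self.shape))


@dataclass
class VoxelMask:
    """A binary voxel mask aligned to a :class:`CTVolume` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cc(self) -> float:
        """Mask volume in cubic centimetres: voxel count x voxel volume."""
        return self.count * float(np.prod(self.spacing)) / 1000.0

    def same_geometry(self, other: "CTVolume | VoxelMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def indices(self) -> np.ndarray:
        """(n, 3) integer array of the voxel indices inside the mask."""
        return np.argwhere(self.data)

    def like(self, data: np.ndarray) -> "VoxelMask":
        """A new mask with the same geometry but different voxels."""
        if data.shape != self.shape:
            raise GeometryError("replacement grid has a different shape")
        return VoxelMask(data, spacing=self.spacing, origin=self.origin)


@dataclass(frozen=True)
class SeedPoint:
    """0-based (x, y, z) voxel index used to seed region growing."""

    x: int
    y: int
    z: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.x, self.y, self.z)

    def check_inside(self, volume: CTVolume) -> None:
        if not volume.contains_index(self.as_tuple()):
            raise IndexError(
                f"seed {self.as_tuple()} outside grid of shape {volume.shape}"
            )
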