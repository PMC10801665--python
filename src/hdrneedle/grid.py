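"""The 3D scalar grid carried through the whole pipeline.

A :class:`Volume` is a plain array with physical metadata.  One coordinate
convention holds project-wide: axis order ``(x, y, z)`` with ``z`` the
slice axis, 0-based voxel indices, and world position in mm

    world = origin + index * spacing.

CT intensities, binary/instance needle masks, probability maps and dose
grids all ride in the same container; only ``data.dtype`` differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Volume:
    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "Volume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def require_same_grid(self, other: "Volume") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch: {self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World mm coordinates of (possibly fractional) voxel indices."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def slice_z_mm(self, k: int) -> float:
        """World z of slice k (z = origin_z + k * spacing_z)."""
        return self.origin[2] + k * self.spacing[2]

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.origin)
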