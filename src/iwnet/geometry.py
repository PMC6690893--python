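"""Grid geometry and user-interaction point types.

Coordinates are 0-based integer voxel indices in ``(x, y, z)`` order, with
``z`` the axial (slice) axis.  All field-map distances are measured in voxel
units on the isotropically resampled grid; the physical spacing is carried
along for metric computations only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

__all__ = ["GridGeometry", "PointPair", "FieldParams"]


@dataclass(frozen=True)
class GridGeometry:
    """Shape and spacing of a voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts per axis ``(nx, ny, nz)``; every entry must be >= 2.
    spacing : tuple of float
        Millimetres per voxel along each axis (informational for the field
        map, which works in voxel units).
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("shape and spacing must have three entries")
        if any(int(s) < 2 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 2, got {self.shape}")
        if any(not (sp > 0) for sp in self.spacing):
            raise ValueError(f"all spacings must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    def contains(self, point) -> bool:
        """True if the integer voxel coordinate lies inside the grid."""
        return all(0 <= int(p) < n for p, n in zip(point, self.shape))


@dataclass(frozen=True)
class PointPair:
    """Two in-bounds voxel coordinates marking a manually drawn diameter.

    The two points are the endpoints of the stroke the user draws across the
    nodule; they anchor the source and sink of the attraction field.
    Coincident points are permitted only as a flagged degenerate case.
    """

    first: Tuple[int, int, int]
    second: Tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "first", tuple(int(p) for p in self.first))
        object.__setattr__(self, "second", tuple(int(p) for p in self.second))
        if len(self.first) != 3 or len(self.second) != 3:
            raise ValueError("points must be 3D voxel coordinates")

    @property
    def coincident(self) -> bool:
        return self.first == self.second

    def validate(self, geometry: GridGeometry) -> None:
        for name, pt in (("first", self.first), ("second", self.second)):
            if not geometry.contains(pt):
                raise ValueError(
                    f"{name} point {pt} outside grid of shape {geometry.shape}"
                )

    def swapped(self) -> "PointPair":
        return PointPair(self.second, self.first)


@dataclass(frozen=True)
class FieldParams:
    """Tunable parameters of the attraction field.

    ``p`` controls the decay of the field vectors' magnitude with distance
    (around 0.5 balances emphasis on the points against the connecting
    region); ``gamma`` thresholds the normalized map into the region of
    interest used by the attraction loss.
    """

    p: float = 0.44
    gamma: float = 0.59

    def __post_init__(self):
        import math

        if not math.isfinite(self.p) or self.p < 0:
            raise ValueError(f"p must be finite and >= 0, got {self.p}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
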