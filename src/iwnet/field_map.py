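"""Two-point attraction weight map.

The interactive guidance signal is modelled on the field of two opposite
point charges placed at the endpoints of the user-drawn nodule diameter.
Each charge contributes a radial vector field whose magnitude follows
``(2 d)**(1 - p)`` with ``d`` the Euclidean voxel distance to the charge;
the superposition ``W = Q0 + Q1`` of the outward (source) and inward (sink)
fields reinforces along the segment between the points and cancels far away.
The scalar map ``M = |W|``, normalized to a maximum of 1, marks how valuable
each voxel is to the segmentation: it is fed to the correction network as an
extra input channel and thresholded (``M > gamma``) into the region of
interest of the attraction loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import GridGeometry, PointPair

__all__ = ["WeightMap", "raw_gradient", "charge_field", "weight_map", "roi_mask"]


@dataclass
class WeightMap:
    """Non-negative scalar guidance map on a voxel grid.

    ``values`` has the geometry's shape; when ``normalized`` the maximum is 1
    unless the map is identically zero (the no-interaction case).
    """

    values: np.ndarray
    normalized: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("weight map must be a 3D grid")
        if np.any(self.values < 0):
            raise ValueError("weight map values must be non-negative")

    @property
    def shape(self):
        return self.values.shape


def _coordinate_grids(geometry: GridGeometry):
    nx, ny, nz = geometry.shape
    return np.meshgrid(
        np.arange(nx, dtype=np.float64),
        np.arange(ny, dtype=np.float64),
        np.arange(nz, dtype=np.float64),
        indexing="ij",
        sparse=True,
    )


def raw_gradient(center, geometry: GridGeometry) -> np.ndarray:
    """Gradient ``2 (r - center)`` of the squared-distance sphere function.

    Evaluated at every voxel center; the singular point at ``center`` maps to
    the zero vector.  Returns an array of shape ``geometry.shape + (3,)``.
    """
    center = tuple(int(c) for c in center)
    if not geometry.contains(center):
        raise ValueError(f"center {center} outside grid of shape {geometry.shape}")
    xs, ys, zs = _coordinate_grids(geometry)
    g = np.empty(geometry.shape + (3,), dtype=np.float64)
    g[..., 0] = 2.0 * (xs - center[0])
    g[..., 1] = 2.0 * (ys - center[1])
    g[..., 2] = 2.0 * (zs - center[2])
    return g


def charge_field(center, a: int, p: float, geometry: GridGeometry) -> np.ndarray:
    """Decayed radial field of a single charge.

    ``Q_a(r) = (-1)**a * u(r) * |G(r)|**(1 - p)`` where ``G`` is the raw
    gradient and ``u`` its unit direction; zero at the charge's own center.
    ``a = 0`` gives the outward (source) field, ``a = 1`` the sink.
    """
    if a not in (0, 1):
        raise ValueError(f"a must be 0 or 1, got {a}")
    if not (np.isfinite(p) and p >= 0):
        raise ValueError(f"p must be finite and >= 0, got {p}")
    g = raw_gradient(center, geometry)
    norm = np.sqrt(np.sum(g * g, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = g / norm[..., None]
        mag = norm ** (1.0 - p)
    field = (-1.0) ** a * unit * mag[..., None]
    field[norm == 0] = 0.0  # singular point convention
    return field


def weight_map(
    points: Optional[PointPair],
    p: float,
    geometry: GridGeometry,
) -> WeightMap:
    """Superpose source and sink fields and take the normalized magnitude.

    With no points the map is identically zero (no interaction, no guidance).
    Swapping the two points flips the sign of ``W`` globally and leaves
    ``M = |W|`` unchanged.
    """
    if points is None:
        return WeightMap(np.zeros(geometry.shape), normalized=True)
    points.validate(geometry)
    if points.coincident:
        warnings.warn(
            "coincident interaction points: source and sink fields cancel, "
            "the weight map is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    w = charge_field(points.first, 0, p, geometry) + charge_field(
        points.second, 1, p, geometry
    )
    m = np.sqrt(np.sum(w * w, axis=-1))
    peak = m.max()
    if peak > 0:
        m = m / peak
    return WeightMap(m, normalized=True)


def roi_mask(map: WeightMap, gamma: float) -> np.ndarray:
    """Binarize the normalized map into the attraction region ``M > gamma``."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if not map.normalized:
        raise ValueError("roi_mask requires a normalized weight map")
    return map.values > gamma
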