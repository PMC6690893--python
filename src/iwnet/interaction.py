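"""Simulated user interaction: farthest boundary points on an axial slice.

Training and evaluation emulate the two endpoints of a manually drawn
nodule diameter by taking the two most distant boundary pixels of the
annotation on a designated axial slice: the median occupied slice during
training, the slice through the mask's center of mass during evaluation.
There is deliberately no attempt to pick points along the direction in
which the segmentation most needs correcting -- the farthest-pair rule is
the harder, assumption-free scenario.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .geometry import PointPair

__all__ = ["select_slice", "boundary_pixels", "farthest_pair", "simulate_user_input"]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def select_slice(mask: np.ndarray, mode: str) -> int:
    """Pick the axial (z) slice on which to simulate the diameter stroke.

    ``train``: median of the z indices of all mask voxels, ties resolved
    downward.  ``eval``: z of the mask's center of mass, rounded to nearest.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3D grid")
    if not mask.any():
        raise ValueError("cannot select a slice of an empty mask")
    zs = np.nonzero(mask)[2]
    if mode == "train":
        zs_sorted = np.sort(zs)
        return int(zs_sorted[(len(zs_sorted) - 1) // 2])
    if mode == "eval":
        return int(np.floor(zs.mean() + 0.5))
    raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")


def boundary_pixels(mask2d: np.ndarray) -> List[Tuple[int, int]]:
    """Mask pixels whose 4-neighbourhood touches background or the border."""
    mask2d = np.asarray(mask2d).astype(bool)
    if mask2d.ndim != 2:
        raise ValueError("expected a 2D slice")
    if not mask2d.any():
        raise ValueError("empty slice has no boundary")
    interior = ndimage.binary_erosion(mask2d, structure=_CROSS, border_value=0)
    xs, ys = np.nonzero(mask2d & ~interior)
    return list(zip(xs.tolist(), ys.tolist()))


def farthest_pair(pixels) -> Tuple[Tuple[int, int], Tuple[int, int], float]:
    """Exhaustive search for the most distant pixel pair.

    Ties are broken by lexicographic order of ``(pA, pB)`` over the sorted
    pixel list, so the result is deterministic for any input ordering.
    """
    pts = sorted(tuple(int(c) for c in p) for p in pixels)
    if len(pts) < 2:
        raise ValueError("farthest_pair needs at least two pixels")
    arr = np.asarray(pts, dtype=np.int64)
    diff = arr[:, None, :] - arr[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    best = d2.max()
    ia, ib = np.argwhere(d2 == best)[0]  # rows in lexicographic order
    if ia > ib:
        ia, ib = ib, ia
    return pts[ia], pts[ib], float(np.sqrt(best))


def simulate_user_input(mask: np.ndarray, mode: str) -> PointPair:
    """Compose slice selection, boundary extraction and the farthest pair.

    The 2D endpoints are lifted back to 3D with the selected z index.
    Raises on masks whose selected slice has fewer than two boundary pixels
    (the caller may skip such nodules).
    """
    z = select_slice(mask, mode)
    pixels = boundary_pixels(np.asarray(mask).astype(bool)[:, :, z])
    if len(pixels) < 2:
        raise ValueError(f"slice z={z} has fewer than two boundary pixels")
    pa, pb, _ = farthest_pair(pixels)
    return PointPair((pa[0], pa[1], z), (pb[0], pb[1], z))
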