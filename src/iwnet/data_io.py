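"""Volume I/O, preprocessing and augmentation.

CT sub-volumes are handled as ``(x, y, z)``-indexed arrays (z axial) with a
millimetre spacing per axis.  Preprocessing follows the cube-extraction
recipe: crop a 51 mm cube around the nodule's consensus center (padding
out-of-scan regions with air, -1000 HU), resample isotropically to 64^3
voxels -- trilinear for images, nearest-neighbour for masks -- and map the
[-1000, 400] HU window linearly onto [0, 1].

Cohorts are described by a CSV manifest with columns ``nodule_id, scan_id,
image_path, mask_paths, texture_ratings`` where ``mask_paths`` and
``texture_ratings`` are semicolon-separated, one entry per annotator.
Paths are resolved relative to the manifest's directory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "VolumeCube",
    "AnnotatedNodule",
    "window_hu",
    "extract_cube",
    "augment",
    "read_volume",
    "write_volume",
    "load_cohort",
    "write_manifest",
]

HU_WINDOW = (-1000.0, 400.0)
CUBE_MM = 51.0
CUBE_VOXELS = 64


@dataclass
class VolumeCube:
    """A 3D scalar grid with voxel spacing, raw-HU or normalized."""

    values: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    normalized: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("volume must be a 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.normalized and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("normalized cube values must lie in [0, 1]")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class AnnotatedNodule:
    """Image cube plus one binary mask per annotator and texture ratings.

    ``agreement_level`` is the number of annotators who segmented the
    nodule; it controls eligibility for the evaluation protocols.
    """

    nodule_id: str
    scan_id: str
    image: VolumeCube
    masks: List[np.ndarray]
    texture_ratings: List[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.masks:
            raise ValueError("a nodule needs at least one annotator mask")
        self.masks = [np.asarray(m).astype(bool) for m in self.masks]
        for m in self.masks:
            if m.shape != self.image.shape:
                raise ValueError("annotator masks must share the image shape")
        if any(not 1.0 <= float(t) <= 5.0 for t in self.texture_ratings):
            raise ValueError("texture ratings must lie in [1, 5]")

    @property
    def agreement_level(self) -> int:
        return len(self.masks)


def window_hu(raw: np.ndarray) -> np.ndarray:
    """Linear [-1000, 400] HU -> [0, 1] mapping, clamped outside the window."""
    raw = np.asarray(raw, dtype=np.float64)
    lo, hi = HU_WINDOW
    return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)


def _resample_to_cube(volume, spacing, center_mm, out_voxels, out_mm, order, cval):
    """Sample a cube of physical side ``out_mm`` centered at ``center_mm``."""
    half = out_mm / 2.0
    step = out_mm / out_voxels
    # voxel centers sit at (index + 0.5) * spacing in physical space
    offs = (np.arange(out_voxels) + 0.5) * step - half
    grids = np.meshgrid(*[(center_mm[a] + offs) / spacing[a] - 0.5
                          for a in range(3)], indexing="ij")
    coords = np.stack(grids)
    return ndimage.map_coordinates(np.asarray(volume, dtype=np.float64), coords,
                                   order=order, mode="constant", cval=cval)


def extract_cube(volume: np.ndarray, spacing, center_mm,
                 masks: Optional[Sequence[np.ndarray]] = None):
    """Crop a 51 mm cube around ``center_mm`` and resample to 64^3.

    The image is interpolated trilinearly, padded with -1000 HU where the
    cube leaves the scan, then intensity-windowed; masks are resampled
    nearest-neighbour (so they stay binary).  Returns a normalized
    :class:`VolumeCube`, or ``(cube, resampled_masks)`` if masks are given.
    """
    volume = np.asarray(volume)
    spacing = tuple(float(s) for s in spacing)
    center_mm = tuple(float(c) for c in center_mm)
    extent_mm = [volume.shape[a] * spacing[a] for a in range(3)]
    if any(not (0.0 <= center_mm[a] <= extent_mm[a]) for a in range(3)):
        raise ValueError(f"center {center_mm} mm lies outside the scan "
                         f"extent {tuple(extent_mm)} mm")
    iso = CUBE_MM / CUBE_VOXELS
    img = _resample_to_cube(volume, spacing, center_mm, CUBE_VOXELS, CUBE_MM,
                            order=1, cval=HU_WINDOW[0])
    cube = VolumeCube(window_hu(img), spacing=(iso, iso, iso), normalized=True)
    if masks is None:
        return cube
    out_masks = [
        _resample_to_cube(m.astype(np.float64), spacing, center_mm, CUBE_VOXELS,
                          CUBE_MM, order=0, cval=0.0).astype(bool)
        for m in masks
    ]
    return cube, out_masks


def augment(image: np.ndarray, masks: Sequence[np.ndarray], seed: int):
    """Apply one random spatial transform to the image and all masks.

    The transform composes a rotation about the axial axis (+-15 degrees), a
    per-axis translation (+-4 voxels), an isotropic zoom in [0.9, 1.1] and
    independent per-axis flips (probability 0.5) -- conservative ranges that
    keep the 51 mm context valid.  Masks use nearest-neighbour
    interpolation; the same seed always yields the same transform.
    """
    rng = np.random.default_rng(seed)
    image = np.asarray(image, dtype=np.float64)
    angle = np.deg2rad(rng.uniform(-15.0, 15.0))
    shift = rng.uniform(-4.0, 4.0, size=3)
    zoom = rng.uniform(0.9, 1.1)
    flips = rng.random(3) < 0.5

    ca, sa = np.cos(angle), np.sin(angle)
    rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    mat = rot / zoom
    for a in range(3):
        if flips[a]:
            mat[:, a] *= -1.0
    center = (np.asarray(image.shape) - 1) / 2.0
    # affine_transform maps output -> input: x_in = mat @ (x_out - c) + c + shift
    offset = center - mat @ center + shift

    out_img = ndimage.affine_transform(image, mat, offset=offset, order=1,
                                       mode="constant", cval=float(image.min()))
    out_masks = [
        ndimage.affine_transform(np.asarray(m, dtype=np.float64), mat,
                                 offset=offset, order=0, mode="constant",
                                 cval=0.0).astype(bool)
        for m in masks
    ]
    return np.clip(out_img, 0.0, 1.0), out_masks


# -- file formats -----------------------------------------------------------

_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_extension(path: str):
    if not str(path).endswith(_EXTENSIONS):
        raise ValueError(
            f"unsupported volume format for {path!r}; expected one of {_EXTENSIONS}")


def read_volume(path):
    """Read a NIfTI/MetaImage volume as an ``(x, y, z)`` array plus spacing."""
    _check_extension(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return np.transpose(arr, (2, 1, 0)), tuple(img.GetSpacing())


def write_volume(grid: np.ndarray, spacing, path):
    """Write an ``(x, y, z)`` array with spacing to NIfTI/MetaImage."""
    _check_extension(path)
    grid = np.asarray(grid)
    if grid.dtype == bool:
        grid = grid.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(grid, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    sitk.WriteImage(img, str(path))


# -- cohort manifests -------------------------------------------------------

MANIFEST_COLUMNS = ["nodule_id", "scan_id", "image_path", "mask_paths",
                    "texture_ratings"]


def write_manifest(rows: Sequence[dict], path):
    """Write a cohort manifest CSV (column layout of :func:`load_cohort`)."""
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def load_cohort(manifest_path, min_agreement: int = 1) -> List[AnnotatedNodule]:
    """Load the nodules of a manifest with agreement level >= ``min_agreement``.

    Every annotator's mask is kept separately -- no consensus merging -- so
    that training can pair the same nodule with each viable ground truth.
    An empty manifest yields an empty cohort.
    """
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    cohort = []
    for idx, row in df.iterrows():
        mask_paths = [p for p in str(row["mask_paths"]).split(";") if p]
        if len(mask_paths) < min_agreement:
            continue
        try:
            image, spacing = read_volume(os.path.join(base, row["image_path"]))
            masks = [read_volume(os.path.join(base, p))[0] > 0 for p in mask_paths]
        except FileNotFoundError as err:
            raise FileNotFoundError(
                f"manifest row {idx} (nodule {row['nodule_id']}): {err}") from err
        ratings = [float(t) for t in str(row["texture_ratings"]).split(";") if t]
        lo, hi = float(image.min()), float(image.max())
        cube = VolumeCube(image, spacing=spacing, normalized=lo >= 0 and hi <= 1)
        cohort.append(AnnotatedNodule(str(row["nodule_id"]), str(row["scan_id"]),
                                      cube, masks, ratings))
    return cohort
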