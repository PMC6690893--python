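"""Segmentation metrics and multi-annotator evaluation protocols.

Predictions are binarized at 0.5 before any metric.  Overlap is measured by
3D intersection over union; boundary accuracy by the average surface
distance (ASD) in millimetres, the symmetric mean of nearest-surface
distances halved across the two directions.  Because each nodule carries
one annotation per expert, model predictions are scored against every
annotator and averaged; the inter-observer agreement -- each annotation
scored against all others -- serves as the practical performance ceiling.
For the interactive protocol the expert keeps the better of the initial and
the corrected segmentation, so the corrected score per annotator is
``max(IoU(S_n, corrected_n), IoU(S_n, initial))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "EvalRecord",
    "iou",
    "asd",
    "mean_iou_vs_annotators",
    "interobserver_iou",
    "corrected_mean_iou",
    "equivalent_radius",
    "texture_class",
    "stratified_report",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class EvalRecord:
    """Per-nodule evaluation summary row."""

    nodule_id: str
    initial_iou: float
    corrected_iou: float
    interobserver: Optional[float]
    initial_asd: float
    corrected_asd: float
    radius_mm: float
    texture: str
    per_annotator_initial: List[float] = field(default_factory=list)
    per_annotator_corrected: List[float] = field(default_factory=list)


def _as_binary(grid) -> np.ndarray:
    grid = np.asarray(grid)
    if grid.dtype == bool:
        return grid
    return grid >= 0.5


def iou(a, b) -> float:
    """3D intersection over union of two masks (soft inputs binarized at 0.5)."""
    a, b = _as_binary(a), _as_binary(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0  # both empty; never triggered by valid cohorts
    return float(np.logical_and(a, b).sum() / union)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    interior = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    return np.argwhere(mask & ~interior)


def asd(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average surface distance in mm between two non-empty masks.

    Surface elements are boundary voxels (6-connectivity); distances are
    Euclidean between voxel centers scaled by the spacing, and the two
    directed means are averaged with weight one half each.
    """
    a, b = _as_binary(a), _as_binary(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("ASD is undefined for an empty mask")
    sp = np.asarray(spacing, dtype=np.float64)
    sa = _surface_voxels(a) * sp
    sb = _surface_voxels(b) * sp
    d_ab = cKDTree(sb).query(sa)[0]
    d_ba = cKDTree(sa).query(sb)[0]
    return 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))


def mean_iou_vs_annotators(annotations: Sequence[np.ndarray], pred) -> float:
    """Mean IoU of one prediction against every annotator's mask."""
    if len(annotations) == 0:
        raise ValueError("need at least one annotation")
    return float(np.mean([iou(s, pred) for s in annotations]))


def interobserver_iou(annotations: Sequence[np.ndarray]) -> float:
    """Average IoU over all ordered (truth, prediction) annotator pairs.

    With N annotators this averages N*(N-1) comparisons; since IoU is
    symmetric it equals the unordered-pair mean.
    """
    n = len(annotations)
    if n < 2:
        raise ValueError("inter-observer agreement needs >= 2 annotations")
    vals = [iou(annotations[i], annotations[j])
            for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def corrected_mean_iou(annotations: Sequence[np.ndarray], initial_pred,
                       corrected_preds: Sequence[np.ndarray]) -> float:
    """Keep-the-better protocol: per annotator, the max of corrected/initial IoU."""
    if len(corrected_preds) != len(annotations):
        raise ValueError("need exactly one corrected prediction per annotator")
    vals = [max(iou(s, c), iou(s, initial_pred))
            for s, c in zip(annotations, corrected_preds)]
    return float(np.mean(vals))


def equivalent_radius(annotations: Sequence[np.ndarray], spacing) -> float:
    """Mean equivalent spherical radius (mm) over the annotators' masks."""
    sp = np.asarray(spacing, dtype=np.float64)
    voxel_mm3 = float(np.prod(sp))
    radii = []
    for m in annotations:
        v = float(_as_binary(m).sum()) * voxel_mm3
        if v > 0:
            radii.append((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0))
    if not radii:
        raise ValueError("all annotations empty")
    return float(np.mean(radii))


def texture_class(ratings: Sequence[float]) -> str:
    """Map texture ratings to a class: mean <= 2 non-solid, == 5 solid, else sub-solid."""
    if len(ratings) == 0:
        raise ValueError("need at least one texture rating")
    mean = float(np.mean(ratings))
    if mean <= 2.0:
        return "non-solid"
    if mean == 5.0:
        return "solid"
    return "sub-solid"


DEFAULT_RADIUS_BINS = np.arange(1.0, 13.0, 1.0)


def stratified_report(records: Sequence[EvalRecord],
                      radius_bins=DEFAULT_RADIUS_BINS) -> pd.DataFrame:
    """Per-radius-bin and per-texture summary of the evaluation records.

    One row per stratum with mean +- sd of initial/corrected IoU and ASD,
    the inter-observer agreement where defined, and the fraction of nodules
    whose corrected IoU strictly exceeds the initial.  Empty strata are
    simply absent from the table.
    """
    if len(records) == 0:
        raise ValueError("no records to report")
    df = pd.DataFrame([{
        "nodule_id": r.nodule_id,
        "initial_iou": r.initial_iou,
        "corrected_iou": r.corrected_iou,
        "interobserver": r.interobserver,
        "initial_asd": r.initial_asd,
        "corrected_asd": r.corrected_asd,
        "radius_mm": r.radius_mm,
        "texture": r.texture,
    } for r in records])
    bins = np.asarray(radius_bins, dtype=np.float64)
    df["radius_bin"] = pd.cut(df["radius_mm"], bins)

    def summarize(group: pd.DataFrame) -> dict:
        return {
            "n": len(group),
            "initial_iou_mean": group["initial_iou"].mean(),
            "initial_iou_sd": group["initial_iou"].std(ddof=0),
            "corrected_iou_mean": group["corrected_iou"].mean(),
            "corrected_iou_sd": group["corrected_iou"].std(ddof=0),
            "interobserver_mean": group["interobserver"].dropna().mean(),
            "initial_asd_mean": group["initial_asd"].mean(),
            "corrected_asd_mean": group["corrected_asd"].mean(),
            "improved_fraction": float(
                (group["corrected_iou"] > group["initial_iou"]).mean()),
        }

    rows = []
    for bin_label, group in df.groupby("radius_bin", observed=True):
        rows.append({"stratum": "radius", "level": str(bin_label), **summarize(group)})
    for tex, group in df.groupby("texture", observed=True):
        rows.append({"stratum": "texture", "level": tex, **summarize(group)})
    rows.append({"stratum": "all", "level": "all", **summarize(df)})
    return pd.DataFrame(rows).round(4)
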