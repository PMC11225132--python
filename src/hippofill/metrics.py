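"""Segmentation quality indices: Dice, IoU, OSR, USR, ASD and Hausdorff distance.

All six indices compare a predicted binary mask against a ground-truth mask of
identical shape and voxel spacing. Overlap metrics are computed from the voxel
confusion counts

    Dice = 2*TP / (R_s + T_s)        IoU = TP / (TP + FP + FN)
    OSR  = FP / (R_s + T_s)          USR = FN / (R_s + T_s)

with R_s = TP + FN (ground-truth foreground) and T_s = TP + FP (predicted
foreground), so that OSR + USR = 1 - Dice holds exactly. Surface distances are
Euclidean in millimetres between the two masks' surface voxel sets: ASD is the
symmetric mean of nearest-surface distances, HD the maximum over both directed
max-min distances.

Degenerate conventions (all total, no exceptions): both masks empty gives
Dice = IoU = 1 and OSR = USR = 0; exactly one empty gives Dice = IoU = 0 with
OSR/USR still defined by the counts; ASD and HD are NaN (flagged) whenever
either mask is empty and such cases are excluded from cohort distance
summaries.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_io import MaskVolume, MetricReport

__all__ = [
    "confusion_counts",
    "dice",
    "iou",
    "osr",
    "usr",
    "surface_voxels",
    "asd",
    "hausdorff",
    "evaluate_case",
]


def _check_compatible(gt: MaskVolume, pred: MaskVolume, check_spacing: bool = True) -> None:
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    if check_spacing and not np.allclose(gt.spacing, pred.spacing):
        raise ValueError(f"spacing mismatch: gt {gt.spacing} vs pred {pred.spacing}")


def confusion_counts(gt: MaskVolume, pred: MaskVolume) -> tuple[int, int, int, int, int]:
    """Voxel counts (tp, fp, fn, r_s, t_s) between ground truth and prediction."""
    _check_compatible(gt, pred)
    g = gt.grid.astype(bool)
    p = pred.grid.astype(bool)
    tp = int(np.count_nonzero(g & p))
    fp = int(np.count_nonzero(~g & p))
    fn = int(np.count_nonzero(g & ~p))
    return tp, fp, fn, tp + fn, tp + fp


def dice(gt: MaskVolume, pred: MaskVolume) -> float:
    """Dice overlap 2*TP/(R_s + T_s); 1 when both masks are empty."""
    tp, _, _, r_s, t_s = confusion_counts(gt, pred)
    if r_s + t_s == 0:
        return 1.0
    return 2.0 * tp / (r_s + t_s)


def iou(gt: MaskVolume, pred: MaskVolume) -> float:
    """Intersection over union TP/(TP+FP+FN); 1 when both masks are empty."""
    tp, fp, fn, _, _ = confusion_counts(gt, pred)
    denom = tp + fp + fn
    if denom == 0:
        return 1.0
    return tp / denom


def osr(gt: MaskVolume, pred: MaskVolume) -> float:
    """Oversegmentation ratio FP/(R_s + T_s); 0 when both masks are empty."""
    _, fp, _, r_s, t_s = confusion_counts(gt, pred)
    if r_s + t_s == 0:
        return 0.0
    return fp / (r_s + t_s)


def usr(gt: MaskVolume, pred: MaskVolume) -> float:
    """Undersegmentation ratio FN/(R_s + T_s); 0 when both masks are empty."""
    _, _, fn, r_s, t_s = confusion_counts(gt, pred)
    if r_s + t_s == 0:
        return 0.0
    return fn / (r_s + t_s)


def surface_voxels(mask: MaskVolume, connectivity: int = 6) -> np.ndarray:
    """Index coordinates (k, 3) of the mask's surface voxels.

    A surface voxel is foreground with at least one background neighbour under
    the given connectivity (default 6 = face adjacency); the volume border
    counts as background, so a single voxel is its own surface.
    """
    if connectivity not in (6, 26):
        raise ValueError("3D surface connectivity must be 6 or 26")
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    fg = mask.grid.astype(bool)
    interior = ndimage.binary_erosion(fg, structure=structure, border_value=0)
    return np.argwhere(fg & ~interior)


def _surface_mm(mask: MaskVolume) -> np.ndarray:
    return surface_voxels(mask) * np.asarray(mask.spacing)[None, :]


def _directed_nearest(from_pts: np.ndarray, to_pts: np.ndarray) -> np.ndarray:
    """Distance from each point of from_pts to its nearest point of to_pts."""
    d, _ = cKDTree(to_pts).query(from_pts, k=1)
    return d


def asd(a: MaskVolume, b: MaskVolume) -> float:
    """Average surface distance in mm; NaN if either mask is empty.

    Symmetric mean of nearest-surface distances:
    (sum_{s in S(A)} d(s, S(B)) + sum_{s in S(B)} d(s, S(A))) / (|S(A)| + |S(B)|).
    """
    _check_compatible(a, b)
    if a.is_empty() or b.is_empty():
        return float("nan")
    sa, sb = _surface_mm(a), _surface_mm(b)
    d_ab = _directed_nearest(sa, sb)
    d_ba = _directed_nearest(sb, sa)
    return float((d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb)))


def hausdorff(a: MaskVolume, b: MaskVolume) -> float:
    """Hausdorff distance in mm, max(h(A,B), h(B,A)) with h the directed
    max-min surface distance; NaN if either mask is empty."""
    _check_compatible(a, b)
    if a.is_empty() or b.is_empty():
        return float("nan")
    sa, sb = _surface_mm(a), _surface_mm(b)
    return float(max(_directed_nearest(sa, sb).max(), _directed_nearest(sb, sa).max()))


def evaluate_case(gt: MaskVolume, pred: MaskVolume, case_id: str | None = None) -> MetricReport:
    """All six indices plus the underlying counts for one gt/pred pair.

    Never raises on empty masks: degenerate conventions are applied and
    recorded in ``degenerate_flags``.
    """
    tp, fp, fn, r_s, t_s = confusion_counts(gt, pred)
    flags: list[str] = []
    if r_s == 0 and t_s == 0:
        flags.append("both_empty")
    elif t_s == 0:
        flags.append("empty_prediction")
    elif r_s == 0:
        flags.append("empty_ground_truth")
    d = dice(gt, pred)
    report = MetricReport(
        dice=d,
        iou=iou(gt, pred),
        osr=osr(gt, pred),
        usr=usr(gt, pred),
        asd=asd(gt, pred),
        hd=hausdorff(gt, pred),
        tp=tp,
        fp=fp,
        fn=fn,
        r_s=r_s,
        t_s=t_s,
        degenerate_flags=tuple(flags + (["surface_undefined"] if (r_s == 0 or t_s == 0) else [])),
        case_id=case_id,
    )
    return report
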