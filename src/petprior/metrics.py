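"""Voxel-level and lesion-level segmentation evaluation.

Voxel-level: Dice overlap, 95th-percentile Hausdorff distance (HD95) and
symmetric average surface distance (ASD), both in physical millimetres.
Lesion-level: tumor components are extracted by 27-connected labelling,
components of 0.3 ml or less are discarded, and detection is scored
per component — a ground-truth lesion counts as detected when the
predicted mask overlaps it (by default in at least one voxel), a
predicted lesion counts as a false positive when it touches no truth
voxel. Recall = TP / (TP + FN) over truth lesions; precision =
TP / (TP + FP) over predicted lesions.

Also here: MTV-group stratified per-lesion Dice, the method-vs-method
false-negative confusion matrix, and the paired two-sided Wilcoxon
signed-rank comparison used for method differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label

from .grid import VolumeGrid

__all__ = [
    "LesionSet",
    "DetectionResult",
    "EvalReport",
    "dice",
    "hd95",
    "asd",
    "extract_lesions",
    "lesion_precision_recall",
    "per_lesion_records",
    "stratified_dice",
    "fn_confusion_matrix",
    "paired_wilcoxon",
    "evaluate",
    "MTV_GROUP_PRESETS",
]

MIN_LESION_VOLUME_ML = 0.3

# Per-disease metabolic-tumor-volume group boundaries (ml). A lesion with
# volume v falls in V1 if v <= b0, V5 if v >= b3, etc.
MTV_GROUP_PRESETS: dict[str, tuple[float, float, float, float]] = {
    "lymphoma": (1.0, 2.0, 4.0, 14.0),
    "lung": (2.0, 3.5, 7.3, 23.0),
    "melanoma": (1.0, 1.5, 3.0, 8.0),
}


def _as_bool(vol: VolumeGrid) -> np.ndarray:
    return np.asarray(vol.values) > 0


def dice(pred: VolumeGrid, truth: VolumeGrid) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1.0."""
    pred.require_same_grid(truth, "pred vs truth")
    a, b = _as_bool(pred), _as_bool(truth)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _surface_points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Surface voxel centers in mm: mask voxels with a 6-neighbour background.

    Voxels on the array boundary count as surface (the outside is
    background).
    """
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    surface = mask & ~interior
    return np.argwhere(surface) * np.asarray(spacing, dtype=float)


def _directed_distances(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    d, _ = cKDTree(q).query(p, k=1)
    return np.asarray(d, dtype=float)


def _pooled_surface_distances(
    pred: VolumeGrid, truth: VolumeGrid
) -> np.ndarray | None:
    pred.require_same_grid(truth, "pred vs truth")
    a, b = _as_bool(pred), _as_bool(truth)
    if not a.any() or not b.any():
        warnings.warn(
            "surface distance undefined for an empty mask; reporting missing",
            stacklevel=3,
        )
        return None
    pa = _surface_points_mm(a, pred.spacing_mm)
    pb = _surface_points_mm(b, truth.spacing_mm)
    return np.concatenate([_directed_distances(pa, pb), _directed_distances(pb, pa)])


def hd95(pred: VolumeGrid, truth: VolumeGrid) -> float:
    """95th percentile of pooled symmetric surface distances, in mm.

    Returns NaN (with a warning) when either mask is empty.
    """
    pooled = _pooled_surface_distances(pred, truth)
    return float("nan") if pooled is None else float(np.percentile(pooled, 95))


def asd(pred: VolumeGrid, truth: VolumeGrid) -> float:
    """Symmetric average surface distance in mm: mean over the union of
    both directed surface-distance multisets. NaN when a mask is empty."""
    pooled = _pooled_surface_distances(pred, truth)
    return float("nan") if pooled is None else float(pooled.mean())


@dataclass
class LesionSet:
    """Connected tumor components of one binary mask.

    Components come from 27-connected labelling; when ``filtered`` is
    set, only components with volume strictly greater than
    ``min_volume_ml`` are retained.
    """

    mask: np.ndarray
    labels: np.ndarray
    component_ids: list[int]
    volumes_ml: list[float]
    mean_suv: list[float] | None
    spacing_mm: tuple[float, float, float]
    min_volume_ml: float
    filtered: bool

    def __len__(self) -> int:
        return len(self.component_ids)

    def component_mask(self, i: int) -> np.ndarray:
        return self.labels == self.component_ids[i]


def extract_lesions(
    mask: VolumeGrid,
    min_volume_ml: float = MIN_LESION_VOLUME_ML,
    suv: VolumeGrid | None = None,
) -> LesionSet:
    """27-connected components of a binary mask, volume-filtered.

    Component volume is voxel count times the voxel volume (spacing
    product) in ml; components with volume <= ``min_volume_ml`` are
    discarded. When an SUV volume is supplied the per-component mean
    uptake is recorded.
    """
    m = _as_bool(mask)
    labels = cc_label(m, connectivity=3)
    vox_ml = mask.voxel_volume_ml
    ids, volumes, means = [], [], []
    for k in range(1, labels.max() + 1):
        comp = labels == k
        vol_ml = float(comp.sum() * vox_ml)
        if vol_ml <= min_volume_ml:
            continue
        ids.append(k)
        volumes.append(vol_ml)
        if suv is not None:
            means.append(float(np.asarray(suv.values)[comp].mean()))
    return LesionSet(
        mask=m,
        labels=labels,
        component_ids=ids,
        volumes_ml=volumes,
        mean_suv=means if suv is not None else None,
        spacing_mm=tuple(mask.spacing_mm),
        min_volume_ml=min_volume_ml,
        filtered=True,
    )


@dataclass
class DetectionResult:
    precision: float
    recall: float
    tp: int
    fn: int
    fp: int
    truth_detected: list[bool] = field(default_factory=list)


def lesion_precision_recall(
    pred_lesions: LesionSet,
    truth_lesions: LesionSet,
    min_overlap_fraction: float = 0.0,
) -> DetectionResult:
    """Lesion-wise detection scores between two lesion sets.

    A truth lesion is detected when the predicted mask overlaps more than
    ``min_overlap_fraction`` of it (the default, 0, means any single
    overlapping voxel counts). A predicted lesion overlapping no truth
    voxel is a false positive. Undefined ratios (no truth lesions, or no
    predicted lesions) are reported as NaN.
    """
    if pred_lesions.mask.shape != truth_lesions.mask.shape:
        raise ValueError("lesion sets must come from the same grid")
    detected = []
    for i in range(len(truth_lesions)):
        comp = truth_lesions.component_mask(i)
        overlap = int((comp & pred_lesions.mask).sum())
        detected.append(overlap > min_overlap_fraction * comp.sum())
    tp = int(sum(detected))
    fn = len(truth_lesions) - tp
    fp = 0
    tp_pred = 0
    for i in range(len(pred_lesions)):
        comp = pred_lesions.component_mask(i)
        if (comp & truth_lesions.mask).any():
            tp_pred += 1
        else:
            fp += 1
    recall = tp / len(truth_lesions) if len(truth_lesions) else float("nan")
    precision = tp_pred / len(pred_lesions) if len(pred_lesions) else float("nan")
    return DetectionResult(
        precision=precision, recall=recall, tp=tp, fn=fn, fp=fp,
        truth_detected=detected,
    )


def _lesion_dice(pred_mask: np.ndarray, comp: np.ndarray) -> float:
    """Dice restricted to the lesion's bounding region (1-voxel pad)."""
    idx = np.argwhere(comp)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, comp.shape)
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    a, b = pred_mask[box], comp[box]
    denom = int(a.sum()) + int(b.sum())
    return 1.0 if denom == 0 else 2.0 * int((a & b).sum()) / denom


def per_lesion_records(
    pred: VolumeGrid,
    truth: VolumeGrid,
    suv: VolumeGrid | None = None,
    min_volume_ml: float = MIN_LESION_VOLUME_ML,
) -> pd.DataFrame:
    """One row per truth lesion: volume, mean SUV, detected flag, Dice.

    Dice is computed within each lesion's bounding region, so one big
    missed lesion elsewhere does not contaminate a small lesion's score.
    """
    truth_lesions = extract_lesions(truth, min_volume_ml, suv=suv)
    pred_lesions = extract_lesions(pred, min_volume_ml)
    det = lesion_precision_recall(pred_lesions, truth_lesions)
    rows = []
    for i in range(len(truth_lesions)):
        comp = truth_lesions.component_mask(i)
        rows.append(
            {
                "lesion": i,
                "volume_ml": truth_lesions.volumes_ml[i],
                "mean_suv": (
                    truth_lesions.mean_suv[i] if truth_lesions.mean_suv else float("nan")
                ),
                "detected": det.truth_detected[i],
                "dice": _lesion_dice(pred_lesions.mask, comp),
            }
        )
    return pd.DataFrame(
        rows, columns=["lesion", "volume_ml", "mean_suv", "detected", "dice"]
    )


def stratified_dice(
    records: pd.DataFrame,
    boundaries: tuple[float, ...] | str = "lymphoma",
    by: str = "volume_ml",
) -> pd.DataFrame:
    """Per-lesion Dice stratified into groups V1..Vk by volume (or uptake).

    ``boundaries`` is either a preset name (per-disease MTV boundaries)
    or an increasing tuple of k-1 edges; a lesion at or below the first
    edge is V1, at or above the last edge is Vk. Empty groups are
    reported with n=0, not as an error.
    """
    if isinstance(boundaries, str):
        boundaries = MTV_GROUP_PRESETS[boundaries]
    edges = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("group boundaries must be strictly increasing")
    values = records[by].to_numpy(dtype=float)
    # v <= edges[0] -> group 0; v >= edges[-1] -> last group
    group_idx = np.digitize(values, edges, right=True)
    group_idx[values >= edges[-1]] = len(edges)
    rows = []
    for g in range(len(edges) + 1):
        sel = records.loc[group_idx == g, "dice"]
        rows.append(
            {
                "group": f"V{g + 1}",
                "n": int(sel.size),
                "dice_mean": float(sel.mean()) if sel.size else float("nan"),
                "dice_std": float(sel.std(ddof=0)) if sel.size else float("nan"),
                "dice_values": sel.tolist(),
            }
        )
    return pd.DataFrame(rows)


def fn_confusion_matrix(
    method_a_pred: VolumeGrid,
    method_b_pred: VolumeGrid,
    truth: VolumeGrid,
    min_volume_ml: float = MIN_LESION_VOLUME_ML,
) -> pd.DataFrame:
    """Cross-tabulate truth-lesion detection by two methods.

    Rows: method A detected Yes/No; columns: method B detected Yes/No.
    Cell counts sum to the number of truth lesions, so disagreement cells
    localize where one method's false negatives are rescued by the other.
    """
    truth_lesions = extract_lesions(truth, min_volume_ml)
    a = _as_bool(method_a_pred)
    b = _as_bool(method_b_pred)
    counts = np.zeros((2, 2), dtype=int)
    for i in range(len(truth_lesions)):
        comp = truth_lesions.component_mask(i)
        det_a = bool((comp & a).any())
        det_b = bool((comp & b).any())
        counts[0 if det_a else 1, 0 if det_b else 1] += 1
    return pd.DataFrame(
        counts,
        index=pd.Index(["Yes", "No"], name="A detected"),
        columns=pd.Index(["Yes", "No"], name="B detected"),
    )


def paired_wilcoxon(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-scan scores.

    Zero differences are dropped before ranking; when every difference is
    zero the comparison is undefined and NaN is returned with a warning.
    The exact null distribution is used for small samples (n <= 25).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = b - a
    nz = diffs[diffs != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p-value undefined")
        return float("nan")
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", alternative="two-sided", method=method
    )
    return float(res.pvalue)


@dataclass
class EvalReport:
    """Voxel-level and lesion-level evaluation of one prediction."""

    dice: float
    hd95_mm: float
    asd_mm: float
    lesion_precision: float
    lesion_recall: float
    tp: int
    fn: int
    fp: int
    per_lesion: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "hd95_mm": self.hd95_mm,
            "asd_mm": self.asd_mm,
            "lesion_precision": self.lesion_precision,
            "lesion_recall": self.lesion_recall,
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
        }


def evaluate(
    pred: VolumeGrid,
    truth: VolumeGrid,
    suv: VolumeGrid | None = None,
    min_volume_ml: float = MIN_LESION_VOLUME_ML,
) -> EvalReport:
    """Full per-scan evaluation: Dice, HD95, ASD, lesion-wise detection."""
    truth_lesions = extract_lesions(truth, min_volume_ml, suv=suv)
    pred_lesions = extract_lesions(pred, min_volume_ml)
    det = lesion_precision_recall(pred_lesions, truth_lesions)
    return EvalReport(
        dice=dice(pred, truth),
        hd95_mm=hd95(pred, truth),
        asd_mm=asd(pred, truth),
        lesion_precision=det.precision,
        lesion_recall=det.recall,
        tp=det.tp,
        fn=det.fn,
        fp=det.fp,
        per_lesion=per_lesion_records(pred, truth, suv=suv, min_volume_ml=min_volume_ml),
    )
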