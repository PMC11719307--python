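"""Hounsfield-unit tissue decomposition and tissue-wise channels.

CT voxels are classified by raw HU into four binary masks:

* bone:    i >= 200
* lean:    -29 <= i <= 150
* adipose: -190 <= i <= -30
* air:     i < -190

The interval boundaries are taken literally: the gap (150, 200) HU between
lean and bone belongs to no tissue (those voxels stay visible only in the
original channels), and -190 HU is adipose, not air. Voxel-wise products
of the masks with the raw CT and the SUV volume give the tissue-wise
channels used as multi-channel projection input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VolumeGrid
from .preprocess import SUV_CLIP, clip_and_normalize

__all__ = ["TissueRuleSet", "TissueChannelSet", "classify_voxels", "make_tissue_channels"]

TISSUES = ("bone", "lean", "adipose", "air")


@dataclass(frozen=True)
class TissueRuleSet:
    """HU thresholds of the four-way tissue decomposition (raw HU)."""

    bone_min: float = 200.0          # inclusive
    lean_range: tuple[float, float] = (-29.0, 150.0)      # inclusive both ends
    adipose_range: tuple[float, float] = (-190.0, -30.0)  # inclusive both ends
    air_max: float = -190.0          # exclusive: i < air_max


@dataclass
class TissueChannelSet:
    """Binary tissue masks plus masked CT/SUV channels on one grid."""

    masks: dict[str, VolumeGrid]
    ct_channels: dict[str, VolumeGrid]
    suv_channels: dict[str, VolumeGrid]
    normalized: bool = False


def classify_voxels(
    ct: VolumeGrid, rules: TissueRuleSet | None = None
) -> dict[str, VolumeGrid]:
    """Decompose a raw-HU CT into bone/lean/adipose/air binary masks.

    The masks are pairwise disjoint; voxels falling in no stated interval
    (e.g. HU in the (150, 200) gap) belong to no mask.
    """
    rules = rules or TissueRuleSet()
    i = ct.values
    masks = {
        "bone": i >= rules.bone_min,
        "lean": (i >= rules.lean_range[0]) & (i <= rules.lean_range[1]),
        "adipose": (i >= rules.adipose_range[0]) & (i <= rules.adipose_range[1]),
        "air": i < rules.air_max,
    }
    return {name: ct.with_values(m.astype(np.uint8)) for name, m in masks.items()}


def _normalize_ct_channel(channel: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Affine map of a masked CT channel's occupied HU range onto [0, 1].

    An all-zero channel (empty mask) and a constant occupied range both
    map to 0 off-mask / well-defined values on-mask without division
    errors.
    """
    out = np.zeros_like(channel, dtype=np.float64)
    occ = mask > 0
    if not occ.any():
        return out
    lo, hi = channel[occ].min(), channel[occ].max()
    if hi > lo:
        out[occ] = (channel[occ] - lo) / (hi - lo)
    else:
        out[occ] = 1.0
    return out


def make_tissue_channels(
    ct: VolumeGrid,
    suv: VolumeGrid,
    masks: dict[str, VolumeGrid] | None = None,
    normalize: bool = True,
) -> TissueChannelSet:
    """Build the tissue-wise CT and SUV channels by voxel-wise masking.

    Each channel is the product of one tissue mask with the raw CT or the
    SUV volume. When ``normalize`` is set, the masked channels are mapped
    onto [0, 1]: SUV channels through the fixed [0, 15] SUV window (so
    uptake stays comparable across patients), CT channels through an
    affine map over each channel's occupied HU range. The original
    CT/SUV volumes are not part of this set and keep their own
    preprocessing.
    """
    ct.require_same_grid(suv, "CT vs SUV")
    if masks is None:
        masks = classify_voxels(ct)
    ct_channels: dict[str, VolumeGrid] = {}
    suv_channels: dict[str, VolumeGrid] = {}
    for name in TISSUES:
        mask = masks[name]
        ct.require_same_grid(mask, f"{name} mask")
        m = mask.values.astype(np.float64)
        ct_masked = ct.values * m
        suv_masked = suv.values * m
        if normalize:
            ct_masked = _normalize_ct_channel(ct_masked, m)
            suv_masked = clip_and_normalize(
                suv.with_values(suv_masked), *SUV_CLIP
            ).values * m
        ct_channels[name] = ct.with_values(ct_masked)
        suv_channels[name] = suv.with_values(suv_masked)
    return TissueChannelSet(
        masks=dict(masks),
        ct_channels=ct_channels,
        suv_channels=suv_channels,
        normalized=normalize,
    )
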