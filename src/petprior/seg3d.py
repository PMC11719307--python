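"""3D segmentation interface: input modes, patching, reference backend.

Three input modes mirror the channel configurations of the 3D stage:
``baseline`` consumes (CT, SUV); ``prior_1`` and ``prior_2`` add a
segmentation prior built from single-channel or 5-channel 2D
segmentations as a third input channel. Inference runs patch-wise with a
sliding window (default 160^3 voxels, 0.25 overlap).

The shipped backend is a deterministic rule-based segmenter: an SUV
threshold generates candidates, and in prior modes voxels supported by
the prior are admitted at a lowered threshold. It is a test instrument —
it makes the benefit of the prior channel measurable end to end without
training — not a clinical model. Neural backends (3D UNet, dynUNet,
nnUNet) can be registered behind the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid
from .prior import SegmentationPrior

__all__ = [
    "Model3DSpec",
    "sliding_window_patches",
    "reference_segmenter3d",
]

MODES = ("baseline", "prior_1", "prior_2")


@dataclass(frozen=True)
class Model3DSpec:
    """Channel mode and patching policy of the 3D segmentation stage."""

    mode: str = "baseline"
    patch_size: tuple[int, int, int] = (160, 160, 160)
    patch_overlap: float = 0.25
    backend: str = "reference"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0 <= self.patch_overlap < 1:
            raise ValueError("patch_overlap must be in [0, 1)")
        if any(p <= 0 for p in self.patch_size):
            raise ValueError("patch_size must be positive")

    @property
    def n_channels(self) -> int:
        return 2 if self.mode == "baseline" else 3


def sliding_window_patches(
    shape: tuple[int, ...],
    patch_size: tuple[int, ...],
    overlap: float = 0.25,
) -> list[tuple[slice, ...]]:
    """Sliding windows covering a volume with the given fractional overlap.

    Stride = patch_size * (1 - overlap) per axis; the final window on each
    axis is clamped to the boundary so the union of windows covers every
    voxel. A patch larger than the volume yields a single window clamped
    to the volume extent.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    per_axis: list[list[tuple[int, int]]] = []
    for n, p in zip(shape, patch_size):
        p_eff = min(p, n)
        stride = max(1, int(round(p_eff * (1 - overlap))))
        offsets = list(range(0, max(n - p_eff, 0) + 1, stride))
        if offsets[-1] != n - p_eff:
            offsets.append(n - p_eff)
        per_axis.append([(o, o + p_eff) for o in offsets])
    windows: list[tuple[slice, ...]] = []
    for ax0 in per_axis[0]:
        for ax1 in per_axis[1]:
            for ax2 in per_axis[2]:
                windows.append(
                    (slice(*ax0), slice(*ax1), slice(*ax2))
                )
    return windows


def reference_segmenter3d(
    spec: Model3DSpec,
    ct: VolumeGrid,
    suv: VolumeGrid,
    prior: SegmentationPrior | None = None,
    suv_threshold: float = 2.0,
    prior_suv_threshold: float = 1.2,
) -> VolumeGrid:
    """Deterministic rule-based 3D segmentation.

    In ``baseline`` mode a voxel is tumor when its SUV is at least
    ``suv_threshold``. In prior modes, voxels with any prior support
    (prior value > 0) are additionally admitted at the lowered
    ``prior_suv_threshold`` — the mechanism by which a faithful prior
    rescues small and faintly avid lesions that a plain uptake rule
    misses. The thresholds are phantom-calibrated defaults on the SUV
    scale (soft-tissue background ~1, lesions >= ~1.5).

    Inference is patch-wise via :func:`sliding_window_patches`; since the
    rule is voxel-wise, overlapping patches agree and are combined by OR.
    """
    ct.require_same_grid(suv, "CT vs SUV")
    if spec.mode != "baseline":
        if prior is None:
            raise ValueError(f"mode {spec.mode!r} requires a segmentation prior")
        suv.require_same_grid(prior.values, "prior")
    out = np.zeros(suv.shape, dtype=np.uint8)
    for window in sliding_window_patches(suv.shape, spec.patch_size, spec.patch_overlap):
        s = suv.values[window]
        patch = s >= suv_threshold
        if spec.mode != "baseline":
            support = prior.values.values[window] > 0
            patch = patch | (support & (s >= prior_suv_threshold))
        out[window] |= patch.astype(np.uint8)
    return suv.with_values(out)
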