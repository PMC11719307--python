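"""2D segmenter contract for the multi-channel multi-angled projections.

The projection-domain tumor segmenter is pluggable: anything exposing
``name``, ``accepts`` (1 for SUVorgMIP-only, 5 for the tissue-wise
multi-channel input) and ``predict(images, angle)`` returning a binary
mask of the projection's shape satisfies the contract. Two deterministic
reference backends ship here — a fixed-SUV threshold segmenter and an
oracle that returns the projected ground truth — so the geometric
pipeline and the prior can be exercised and bounded without any trained
network. A neural 2D backend (e.g. a UNet++ trained with Dice+Focal loss)
can be registered behind the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projection import ProjectionStack

__all__ = [
    "Segmenter2D",
    "ThresholdSegmenter2D",
    "OracleSegmenter2D",
    "EnsembleSegmenter2D",
    "threshold_segmenter",
    "oracle_segmenter",
    "predict_stack",
    "register_backend",
    "get_backend",
]


class Segmenter2D:
    """Base contract: map one multi-channel 2D projection to a binary mask."""

    name: str = "abstract"
    accepts: int = 5

    def predict(self, images: dict[str, np.ndarray], angle: float) -> np.ndarray:
        raise NotImplementedError


@dataclass
class ThresholdSegmenter2D(Segmenter2D):
    """Threshold the SUVorgMIP channel at a fixed SUV value.

    A deterministic single-channel stand-in for the trained 2D network;
    pixels strictly above the threshold are foreground.
    """

    threshold: float = 2.5
    name: str = "threshold"
    accepts: int = 1

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")

    def predict(self, images: dict[str, np.ndarray], angle: float) -> np.ndarray:
        return (images["SUVorgMIP"] > self.threshold).astype(np.uint8)


class OracleSegmenter2D(Segmenter2D):
    """Return the projected ground-truth mask at every angle.

    An upper-bound 2D stage: downstream prior quality with this segmenter
    bounds what any trained backend can achieve on the same scan.
    """

    name = "oracle"
    accepts = 5

    def __init__(self, stack: ProjectionStack):
        if stack.gt_masks is None:
            raise ValueError("oracle segmenter requires a stack with ground-truth masks")
        self._gt = stack.gt_masks

    def predict(self, images: dict[str, np.ndarray], angle: float) -> np.ndarray:
        if angle not in self._gt:
            raise KeyError(f"no ground-truth mask recorded at angle {angle}")
        return self._gt[angle].astype(np.uint8).copy()


class EnsembleSegmenter2D(Segmenter2D):
    """Pixel-wise OR of several segmenters (maximize detected lesions).

    Combining a disease-specific and a generally trained network this way
    keeps every lesion either one finds; filtering apparent false
    positives is left to the member backends.
    """

    name = "ensemble"

    def __init__(self, members: list[Segmenter2D]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members
        self.accepts = max(m.accepts for m in members)

    def predict(self, images: dict[str, np.ndarray], angle: float) -> np.ndarray:
        out = None
        for m in self.members:
            mask = m.predict(images, angle)
            out = mask if out is None else (out | mask)
        return out.astype(np.uint8)


def threshold_segmenter(threshold: float) -> ThresholdSegmenter2D:
    """A segmenter thresholding the SUVorgMIP channel (strictly above)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return ThresholdSegmenter2D(threshold=threshold)


def oracle_segmenter(stack: ProjectionStack) -> OracleSegmenter2D:
    """A segmenter that replays the stack's projected ground truth."""
    return OracleSegmenter2D(stack)


def predict_stack(
    segmenter: Segmenter2D, stack: ProjectionStack
) -> dict[float, np.ndarray]:
    """Run a 2D segmenter over every angle of a projection stack.

    Returns one binary mask per angle, shape-matched to the stack's
    per-angle images. Single-channel segmenters see only SUVorgMIP.
    """
    if segmenter.accepts not in (1, 5):
        raise ValueError(f"segmenter must accept 1 or 5 channels, got {segmenter.accepts}")
    channels = ("SUVorgMIP",) if segmenter.accepts == 1 else stack.channel_names
    masks: dict[float, np.ndarray] = {}
    for angle in stack.angles:
        images = stack.images_at(angle, channels)
        mask = np.asarray(segmenter.predict(images, angle))
        ref_shape = images["SUVorgMIP"].shape
        if mask.shape != ref_shape:
            raise ValueError(
                f"segmenter {segmenter.name!r} returned shape {mask.shape} "
                f"at angle {angle}, expected {ref_shape}"
            )
        if not np.all(np.isin(np.unique(mask), (0, 1))):
            raise ValueError(f"segmenter {segmenter.name!r} returned a non-binary mask")
        masks[angle] = mask.astype(np.uint8)
    return masks


_BACKENDS: dict[str, type] = {
    "threshold": ThresholdSegmenter2D,
    "oracle": OracleSegmenter2D,
    "ensemble": EnsembleSegmenter2D,
}


def register_backend(name: str, cls: type) -> None:
    """Register a 2D segmenter backend (e.g. a neural model wrapper)."""
    _BACKENDS[name] = cls


def get_backend(name: str) -> type:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise KeyError(
            f"unknown 2D segmenter backend {name!r}; known: {sorted(_BACKENDS)}"
        ) from None
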