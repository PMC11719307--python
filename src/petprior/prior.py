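"""Backprojection and fusion of 2D lesion masks into a segmentation prior.

Each per-angle 2D mask is extruded along its ray direction into the
padded rotated frame, inverse-rotated back to the source orientation with
nearest-neighbour resampling (so per-angle contributions stay binary),
and cropped to the source grid. Summing the 18 binary volumes gives a
per-voxel overlap count in 0..18; multiplying by the SUV volume weights
regions where many views agree AND uptake is high. The result is max-
normalized to [0, 1] and the bottom 5th percentile of its positive values
is zeroed as a noise floor, yielding the segmentation prior that can be
fed to a 3D segmenter as an extra input channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from .grid import VolumeGrid
from .projection import ProjectionStack, pad_geometry, rotate_inplane

__all__ = [
    "SegmentationPrior",
    "backproject_mask",
    "fuse_backprojections",
    "finalize_prior",
    "build_prior",
    "prior_localization_score",
]


@dataclass
class SegmentationPrior:
    """The fused, SUV-weighted, normalized 3D backprojection volume.

    ``provenance`` records which 2D segmenter family produced the masks:
    ``prior_1`` for a single-channel (SUVorgMIP-only) segmenter,
    ``prior_2`` for the 5-channel tissue-wise segmenter.
    """

    values: VolumeGrid
    n_angles_used: int
    provenance: str = "prior_2"
    noise_floor_percentile: float = 5.0


def backproject_mask(
    mask2d: np.ndarray,
    angle: float,
    source_shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VolumeGrid:
    """Extrude a 2D projection-domain mask back into the 3D source frame.

    The mask (shape: z extent x padded in-plane extent) is replicated
    along the ray (anterior-posterior) axis of the rotated frame,
    inverse-rotated by ``-angle`` about the same in-plane center with
    nearest-neighbour interpolation, and cropped to ``source_shape``.
    The output is binary.
    """
    mask2d = np.asarray(mask2d)
    if not np.all(np.isin(np.unique(mask2d), (0, 1))):
        raise ValueError("backprojection requires a binary 2D mask")
    p, ox, oy = pad_geometry(source_shape)
    nz = source_shape[2]
    if mask2d.shape != (nz, p):
        raise ValueError(
            f"mask shape {mask2d.shape} does not match projection geometry "
            f"({nz}, {p}) of source shape {source_shape}"
        )
    # extruded[x, y, z] = mask2d[z, x] for every y
    extruded = np.broadcast_to(
        mask2d.T.astype(np.float64)[:, None, :], (p, p, nz)
    ).copy()
    restored = rotate_inplane(extruded, -angle, order=0)
    nx, ny = source_shape[0], source_shape[1]
    cropped = restored[ox : ox + nx, oy : oy + ny, :]
    return VolumeGrid((cropped > 0.5).astype(np.uint8), spacing_mm)


def fuse_backprojections(
    volumes: list[VolumeGrid], suv: VolumeGrid
) -> VolumeGrid:
    """Sum per-angle binary backprojections and weight by SUV voxel-wise."""
    if not volumes:
        raise ValueError("need at least one backprojected volume")
    total = np.zeros(suv.shape, dtype=np.float64)
    for vol in volumes:
        suv.require_same_grid(vol, "backprojection")
        total += vol.values
    return suv.with_values(total * suv.values)


def finalize_prior(
    fused: VolumeGrid,
    percentile: float = 5.0,
    n_angles_used: int = 0,
    provenance: str = "prior_2",
    positive_only: bool = True,
) -> SegmentationPrior:
    """Normalize a fused volume to [0, 1] and remove the noise floor.

    Values are scaled by the global maximum; afterwards every voxel at or
    below the ``percentile``-th percentile of the strictly positive
    values is set to zero. The percentile is taken over the positive
    support by default because the overwhelming majority of voxels lie
    outside every extrusion and are exactly zero (set
    ``positive_only=False`` for an all-voxel percentile). An all-zero
    input yields an all-zero prior.
    """
    v = np.asarray(fused.values, dtype=np.float64)
    if np.any(v < 0):
        raise ValueError("fused volume must be non-negative")
    vmax = v.max()
    if vmax > 0:
        v = v / vmax
        pool = v[v > 0] if positive_only else v
        if pool.size:
            floor = np.percentile(pool, percentile)
            # strict cut: percentile 0 removes nothing; 5 removes exactly
            # the bottom 5% of (distinct) positive values
            v = np.where(v < floor, 0.0, v)
    return SegmentationPrior(
        values=fused.with_values(v),
        n_angles_used=n_angles_used,
        provenance=provenance,
        noise_floor_percentile=percentile,
    )


def build_prior(
    masks: dict[float, np.ndarray],
    stack: ProjectionStack,
    suv: VolumeGrid,
    percentile: float = 5.0,
    provenance: str = "prior_2",
) -> SegmentationPrior:
    """Backproject per-angle masks, fuse with SUV, and finalize."""
    volumes = [
        backproject_mask(masks[angle], angle, stack.source_shape, stack.spacing_mm)
        for angle in stack.angles
    ]
    fused = fuse_backprojections(volumes, suv)
    return finalize_prior(
        fused, percentile, n_angles_used=len(volumes), provenance=provenance
    )


def prior_localization_score(prior: SegmentationPrior, truth: VolumeGrid) -> float:
    """Fraction of truth lesions highlighted by the prior.

    A lesion (27-connected truth component) counts as highlighted when the
    prior value at its centroid voxel is strictly above the median prior
    value outside the truth mask. The score is rank-based, hence invariant
    to monotone rescaling of the prior.
    """
    prior.values.require_same_grid(truth, "truth")
    t = np.asarray(truth.values) > 0
    labels = cc_label(t, connectivity=3)
    n = labels.max()
    if n == 0:
        raise ValueError("localization score undefined for an empty truth mask")
    pv = np.asarray(prior.values.values)
    background_median = float(np.median(pv[~t]))
    hits = 0
    for k in range(1, n + 1):
        coords = np.argwhere(labels == k)
        centroid = tuple(np.round(coords.mean(axis=0)).astype(int))
        if pv[centroid] > background_median:
            hits += 1
    return hits / n
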