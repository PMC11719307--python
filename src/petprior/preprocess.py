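"""CT/SUV conditioning: SUV conversion, resampling, clipping, normalization.

The model-ready representation clips CT to [-100, 250] HU and SUV to
[0, 15], then maps both windows affinely onto [0, 1]. Tissue
classification (see :mod:`petprior.tissue`) must run on the ORIGINAL HU
values, before this step, because its thresholds (-190, 200 HU) lie
outside the CT clip window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid

__all__ = [
    "PreprocessSpec",
    "compute_suv",
    "resample_to_common_grid",
    "clip_and_normalize",
    "preprocess_pair",
]

CT_CLIP = (-100.0, 250.0)
SUV_CLIP = (0.0, 15.0)


@dataclass(frozen=True)
class PreprocessSpec:
    """Target grid and intensity windows for model-ready volumes."""

    target_spacing_mm: tuple[float, float, float] = (2.04, 2.04, 3.00)
    ct_clip: tuple[float, float] = CT_CLIP
    suv_clip: tuple[float, float] = SUV_CLIP

    def __post_init__(self) -> None:
        for lo, hi in (self.ct_clip, self.suv_clip):
            if not lo < hi:
                raise ValueError(f"clip window must satisfy low < high, got ({lo}, {hi})")


def compute_suv(
    pet_activity: VolumeGrid, injected_dose_bq: float, body_weight_kg: float
) -> VolumeGrid:
    """Convert PET activity concentration (Bq/ml) to body-weight SUV.

    SUV = activity [Bq/ml] * body weight [g] / injected dose [Bq]; the
    result is dimensionless under the usual 1 g/ml tissue-density
    assumption. Decay correction of the dose is the caller's concern.
    """
    if injected_dose_bq <= 0:
        raise ValueError(f"injected dose must be positive, got {injected_dose_bq}")
    if body_weight_kg <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_kg}")
    factor = body_weight_kg * 1000.0 / injected_dose_bq
    return pet_activity.with_values(pet_activity.values * factor)


def resample_to_common_grid(
    vol: VolumeGrid,
    spec: PreprocessSpec | None = None,
    mode: str = "continuous",
) -> VolumeGrid:
    """Resample a volume to the target spacing.

    ``mode='continuous'`` uses linear interpolation; ``mode='label'`` uses
    nearest-neighbour so binary masks stay binary. Volumes already on the
    target spacing are returned unchanged (identity resample).
    """
    if mode not in ("continuous", "label"):
        raise ValueError(f"mode must be 'continuous' or 'label', got {mode!r}")
    spec = spec or PreprocessSpec()
    target = np.asarray(spec.target_spacing_mm, dtype=float)
    current = np.asarray(vol.spacing_mm, dtype=float)
    if np.allclose(current, target):
        return vol
    zoom = current / target
    out_shape = np.round(np.asarray(vol.shape) * zoom).astype(int)
    if np.any(out_shape < 1):
        raise ValueError(
            f"resampling {vol.shape}@{tuple(current)} to {tuple(target)} mm "
            "yields an empty grid"
        )
    order = 1 if mode == "continuous" else 0
    out = ndimage.zoom(
        np.asarray(vol.values, dtype=np.float64),
        zoom,
        order=order,
        mode="nearest",
        grid_mode=False,
    )
    return VolumeGrid(out, tuple(target), vol.origin_mm)


def clip_and_normalize(vol: VolumeGrid, lo: float, hi: float) -> VolumeGrid:
    """Clamp values to [lo, hi] and map affinely so lo -> 0 and hi -> 1."""
    if not lo < hi:
        raise ValueError(f"require lo < hi, got ({lo}, {hi})")
    v = np.clip(vol.values, lo, hi)
    return vol.with_values((v - lo) / (hi - lo))


def preprocess_pair(
    ct: VolumeGrid, suv: VolumeGrid, spec: PreprocessSpec | None = None
) -> tuple[VolumeGrid, VolumeGrid]:
    """Resample then clip/normalize a CT/SUV pair to model-ready form.

    Resampling happens before clipping so interpolation never straddles
    the hard clip boundary.
    """
    spec = spec or PreprocessSpec()
    ct = resample_to_common_grid(ct, spec, mode="continuous")
    suv = resample_to_common_grid(suv, spec, mode="continuous")
    return (
        clip_and_normalize(ct, *spec.ct_clip),
        clip_and_normalize(suv, *spec.suv_clip),
    )
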