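"""Multi-channel multi-angled maximum intensity projections.

A projection at angle ``theta`` rotates the volume by ``theta`` degrees
about the craniocaudal (z) axis — counter-clockwise from +x toward +y in
index space, centered on the in-plane grid center — and then reduces the
rotated volume by maximum along the anterior-posterior (y) axis. Angle 0
is therefore a coronal MIP, the standard whole-body PET convention. The
schedule [-90°, 90°) at 10° steps yields 18 views per scan.

Volumes are padded in-plane to the diagonal before rotation so no anatomy
leaves the field of view at oblique angles; projection images keep the
padded width, and the original grid shape recorded on the stack lets the
backprojection stage invert the geometry exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid
from .tissue import TISSUES, TissueChannelSet

__all__ = [
    "AngleSchedule",
    "ProjectionStack",
    "enumerate_angles",
    "mip_at_angle",
    "build_projection_stack",
    "save_stack",
    "load_stack",
]

CHANNEL_NAMES = ("SUVorgMIP", "SUVboneMIP", "SUVleanMIP", "SUVadiposeMIP", "SUVairMIP")

PAD_MARGIN = 2  # extra in-plane voxels beyond the diagonal


@dataclass(frozen=True)
class AngleSchedule:
    """Half-open arithmetic sequence of projection angles in degrees."""

    start_deg: float = -90.0
    stop_deg: float = 90.0
    step_deg: float = 10.0
    angles: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.step_deg <= 0:
            raise ValueError(f"step must be positive, got {self.step_deg}")
        if not self.start_deg < self.stop_deg:
            raise ValueError("require start < stop")
        n = int(np.ceil((self.stop_deg - self.start_deg) / self.step_deg - 1e-12))
        angles = tuple(float(self.start_deg + k * self.step_deg) for k in range(n))
        object.__setattr__(self, "angles", angles)

    def __len__(self) -> int:
        return len(self.angles)

    def __iter__(self):
        return iter(self.angles)


def enumerate_angles(
    start: float = -90.0, stop: float = 90.0, step: float = 10.0
) -> AngleSchedule:
    """Build the projection angle schedule [start, stop) at the given step."""
    return AngleSchedule(start, stop, step)


def pad_geometry(shape: tuple[int, int, int]) -> tuple[int, int, int]:
    """(padded in-plane size P, x offset, y offset) for a source shape.

    P covers the in-plane diagonal plus a safety margin, so any rotation
    keeps the original content inside the padded frame.
    """
    nx, ny = shape[0], shape[1]
    p = int(np.ceil(np.hypot(nx, ny))) + PAD_MARGIN
    return p, (p - nx) // 2, (p - ny) // 2


def _pad_inplane(values: np.ndarray) -> np.ndarray:
    p, ox, oy = pad_geometry(values.shape)
    nx, ny = values.shape[0], values.shape[1]
    out = np.zeros((p, p, values.shape[2]), dtype=np.float64)
    out[ox : ox + nx, oy : oy + ny, :] = values
    return out


def rotate_inplane(values: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    """Rotate a (square in-plane) volume about z by ``angle_deg`` CCW.

    Multiples of 90° are exact array rotations (no interpolation); other
    angles use an affine resampling of the given spline order around the
    in-plane center ((P-1)/2, (P-1)/2).
    """
    if values.shape[0] != values.shape[1]:
        raise ValueError("rotate_inplane expects a square in-plane frame")
    angle = float(angle_deg) % 360.0
    if angle % 90.0 == 0.0:
        return np.rot90(values, k=int(round(angle / 90.0)), axes=(0, 1)).copy()
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # output[o] = input[M (o - center) + center] with M = R(-theta)
    m = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    center = np.array([(values.shape[0] - 1) / 2.0, (values.shape[1] - 1) / 2.0, 0.0])
    offset = center - m @ center
    return ndimage.affine_transform(
        values, m, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=(order > 1),
    )


def mip_at_angle(vol: VolumeGrid, angle: float, mode: str = "max") -> np.ndarray:
    """Maximum intensity projection of a volume at one viewing angle.

    Returns a 2D array of shape (z extent, padded in-plane extent):
    row = slice index along z, column = in-plane position after rotation.

    ``mode='max'`` rotates with linear interpolation and is meant for
    intensity volumes. ``mode='mask'`` requires a binary input and
    returns a binary "any tumor along the ray" image: the mask is rotated
    with linear interpolation and every strictly positive projected pixel
    counts as foreground, which guarantees that no foreground voxel is
    ever lost to resampling at oblique angles.
    """
    if mode not in ("max", "mask"):
        raise ValueError(f"mode must be 'max' or 'mask', got {mode!r}")
    values = np.asarray(vol.values, dtype=np.float64)
    if mode == "mask":
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError("mask-mode projection requires a binary volume")
    padded = _pad_inplane(values)
    rotated = rotate_inplane(padded, angle, order=1)
    image = rotated.max(axis=1).T  # (z, in-plane)
    if mode == "mask":
        image = (image > 0).astype(np.uint8)
    return image


@dataclass
class ProjectionStack:
    """Per-angle, per-channel MIP images plus projected truth masks."""

    angles: AngleSchedule
    channel_names: tuple[str, ...]
    images: dict[float, dict[str, np.ndarray]]
    gt_masks: dict[float, np.ndarray] | None
    source_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]

    @property
    def n_images(self) -> int:
        return sum(len(per_angle) for per_angle in self.images.values())

    def images_at(self, angle: float, channels: tuple[str, ...] | None = None):
        per_angle = self.images[angle]
        names = channels or self.channel_names
        return {name: per_angle[name] for name in names}


def build_projection_stack(
    channels: TissueChannelSet,
    suv_orig: VolumeGrid,
    truth: VolumeGrid | None = None,
    schedule: AngleSchedule | None = None,
) -> ProjectionStack:
    """Project the 5 SUV channels (and optionally the truth mask) at every
    scheduled angle.

    The five channels are the original SUV plus the bone/lean/adipose/air
    tissue-wise SUV channels; the truth mask, when supplied, is projected
    in mask mode so each angle carries a 2D "any tumor along the ray"
    label image.
    """
    schedule = schedule or enumerate_angles()
    for name in TISSUES:
        suv_orig.require_same_grid(channels.suv_channels[name], f"SUV channel {name}")
    if truth is not None:
        suv_orig.require_same_grid(truth, "truth")
    volumes = {"SUVorgMIP": suv_orig}
    for name in TISSUES:
        volumes[f"SUV{name}MIP"] = channels.suv_channels[name]

    images: dict[float, dict[str, np.ndarray]] = {}
    gt_masks: dict[float, np.ndarray] | None = {} if truth is not None else None
    for angle in schedule:
        images[angle] = {
            cname: mip_at_angle(vol, angle, mode="max")
            for cname, vol in volumes.items()
        }
        if truth is not None:
            gt_masks[angle] = mip_at_angle(truth, angle, mode="mask")
    return ProjectionStack(
        angles=schedule,
        channel_names=CHANNEL_NAMES,
        images=images,
        gt_masks=gt_masks,
        source_shape=tuple(suv_orig.shape),
        spacing_mm=tuple(suv_orig.spacing_mm),
    )


def save_stack(stack: ProjectionStack, path) -> None:
    """Serialize a stack as one compressed .npz with a JSON manifest."""
    arrays: dict[str, np.ndarray] = {}
    for ai, angle in enumerate(stack.angles):
        for cname in stack.channel_names:
            arrays[f"img_{ai:02d}_{cname}"] = stack.images[angle][cname]
        if stack.gt_masks is not None:
            arrays[f"gt_{ai:02d}"] = stack.gt_masks[angle]
    manifest = {
        "angles": list(stack.angles.angles),
        "schedule": [stack.angles.start_deg, stack.angles.stop_deg, stack.angles.step_deg],
        "channels": list(stack.channel_names),
        "source_shape": list(stack.source_shape),
        "spacing_mm": list(stack.spacing_mm),
        "has_gt": stack.gt_masks is not None,
    }
    arrays["manifest"] = np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **arrays)


def load_stack(path) -> ProjectionStack:
    with np.load(str(path)) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        schedule = AngleSchedule(*manifest["schedule"])
        images: dict[float, dict[str, np.ndarray]] = {}
        gt: dict[float, np.ndarray] | None = {} if manifest["has_gt"] else None
        for ai, angle in enumerate(schedule):
            images[angle] = {
                cname: data[f"img_{ai:02d}_{cname}"] for cname in manifest["channels"]
            }
            if gt is not None:
                gt[angle] = data[f"gt_{ai:02d}"]
    return ProjectionStack(
        angles=schedule,
        channel_names=tuple(manifest["channels"]),
        images=images,
        gt_masks=gt,
        source_shape=tuple(manifest["source_shape"]),
        spacing_mm=tuple(manifest["spacing_mm"]),
    )
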