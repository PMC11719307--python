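"""Synthetic whole-body PET/CT phantoms.

Generates paired CT (HU), SUV, and ground-truth lesion volumes with the
anatomical structure the projection/backprojection pipeline assumes: a
body-shaped elliptic cylinder containing adipose, lean, and bone
compartments surrounded by air, a low-uptake SUV background with optional
physiologic hot spots, and ellipsoidal lesions of configurable count, size
and uptake. Everything is driven by a single RNG seed and is bit-identical
across runs for a fixed configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.measure import label as cc_label

from .grid import VolumeGrid, save_nifti

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "generate_phantom",
    "lesion_truth_volumes_ml",
    "hard_case_config",
]

DEFAULT_TISSUE_HU = {"bone": 400.0, "lean": 40.0, "adipose": -100.0, "air": -800.0}


class LesionPlacementError(RuntimeError):
    """Raised when a lesion cannot be placed inside the body without overlap."""


@dataclass
class PhantomConfig:
    """Configuration of a synthetic PET/CT phantom.

    Attributes
    ----------
    grid_shape : voxel counts along (x, y, z).
    voxel_spacing_mm : physical voxel size; default matches a typical
        whole-body FDG-PET grid of 2.04 x 2.04 x 3.00 mm.
    body_axes_mm : in-plane semi-axes of the elliptic-cylinder body.
    n_lesions : number of tumor lesions to place.
    lesion_radius_range_mm : (min, max) isotropic lesion radius in mm.
    lesion_suv_range : (min, max) lesion uptake; the minimum must exceed
        ``background_suv`` so lesions are separable from background.
    lesion_specs : optional explicit list of (radius_mm, suv) pairs; when
        given it overrides the random ranges and fixes ``n_lesions``.
    background_suv : mean soft-tissue background uptake.
    noise_sd : additive Gaussian noise scale on SUV (clipped at 0).
    ct_noise_sd_hu : additive Gaussian noise scale on CT in HU.
    tissue_hu_means : HU means for the bone/lean/adipose/air compartments.
    n_hotspots : physiologic high-uptake regions (e.g. bladder-like) that
        are NOT part of the tumor ground truth.
    hotspot_suv : uptake of the physiologic hot spots.
    seed : RNG seed; a fixed seed makes the output bit-identical.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: tuple[float, float, float] = (2.04, 2.04, 3.00)
    body_axes_mm: tuple[float, float] = (55.0, 42.0)
    n_lesions: int = 3
    lesion_radius_range_mm: tuple[float, float] = (5.0, 11.0)
    lesion_suv_range: tuple[float, float] = (2.5, 8.0)
    lesion_specs: list[tuple[float, float]] | None = None
    background_suv: float = 1.0
    noise_sd: float = 0.05
    ct_noise_sd_hu: float = 10.0
    tissue_hu_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    n_hotspots: int = 1
    hotspot_suv: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid shape must be positive")
        if any(a <= 0 for a in self.body_axes_mm):
            raise ValueError("body axes must be positive")
        if self.lesion_specs is not None:
            self.n_lesions = len(self.lesion_specs)
            min_suv = min((s for _, s in self.lesion_specs), default=np.inf)
        else:
            min_suv = self.lesion_suv_range[0]
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be non-negative")
        if self.n_lesions > 0 and min_suv <= self.background_suv:
            raise ValueError(
                f"minimum lesion SUV ({min_suv}) must exceed background_suv "
                f"({self.background_suv})"
            )


@dataclass
class PhantomSample:
    """A generated phantom: CT, SUV, binary truth, and the lesion catalog.

    ``lesion_catalog`` holds one ``(centroid_voxel, radius_mm, mean_suv)``
    tuple per placed lesion.
    """

    ct: VolumeGrid
    suv: VolumeGrid
    truth: VolumeGrid
    lesion_catalog: list[tuple[tuple[int, int, int], float, float]]

    @property
    def body_mask(self) -> np.ndarray:
        """Voxels inside the body (CT above the air compartment)."""
        return self.ct.values > -400.0


def _ellipsoid_mask(shape, center_vox, radii_vox) -> np.ndarray:
    grids = np.ogrid[[slice(0, n) for n in shape]]
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_vox, radii_vox))
    return d2 <= 1.0


def _body_mask(config: PhantomConfig) -> np.ndarray:
    nx, ny, nz = config.grid_shape
    sx, sy, _ = config.voxel_spacing_mm
    ax, ay = config.body_axes_mm
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = (np.arange(nx)[:, None] - cx) * sx
    y = (np.arange(ny)[None, :] - cy) * sy
    inplane = (x / ax) ** 2 + (y / ay) ** 2 <= 1.0
    return np.repeat(inplane[:, :, None], nz, axis=2)


def _place_blobs(
    rng: np.random.Generator,
    config: PhantomConfig,
    specs: list[tuple[float, float]],
    occupied: list[tuple[np.ndarray, float]],
    what: str,
    max_tries: int = 200,
):
    """Place ellipsoidal blobs fully inside the body without mutual overlap.

    ``occupied`` accumulates (centroid_mm, radius_mm) of already-placed
    blobs; new blobs keep a 1-voxel-diagonal margin from each of them.
    """
    nx, ny, nz = config.grid_shape
    sx, sy, sz = config.voxel_spacing_mm
    ax, ay = config.body_axes_mm
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    margin_mm = float(np.linalg.norm(config.voxel_spacing_mm))
    placed = []
    for idx, (radius_mm, suv) in enumerate(specs):
        ok = False
        for _ in range(max_tries):
            # sample in-plane inside the body ellipse shrunk by the radius
            u, v = rng.uniform(-1, 1, size=2)
            if u * u + v * v > 1.0:
                continue
            px = u * max(ax - radius_mm, 1e-6)
            py = v * max(ay - radius_mm, 1e-6)
            if (px / ax) ** 2 + (py / ay) ** 2 > (1 - radius_mm / min(ax, ay)) ** 2:
                continue
            rz_vox = radius_mm / sz
            if nz - 1 - 2 * rz_vox <= 0:
                continue
            pz_vox = rng.uniform(rz_vox + 0.5, nz - 1.5 - rz_vox)
            center_mm = np.array([px, py, pz_vox * sz])
            if any(
                np.linalg.norm(center_mm - c) < radius_mm + r + margin_mm
                for c, r in occupied
            ):
                continue
            center_vox = (
                cx + px / sx,
                cy + py / sy,
                pz_vox,
            )
            occupied.append((center_mm, radius_mm))
            placed.append((center_vox, radius_mm, suv))
            ok = True
            break
        if not ok:
            raise LesionPlacementError(
                f"could not place {what} {idx} (radius {radius_mm} mm) inside "
                f"the body after {max_tries} attempts"
            )
    return placed


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Generate a paired CT/SUV/truth phantom from ``config``.

    The body interior is decomposed into an adipose outer shell, a lean
    core, and a bone "spine" column, each at its configured HU mean plus
    Gaussian noise; the exterior sits at the air HU. The SUV volume has a
    low-uptake background inside the body, near-zero uptake outside,
    optional physiologic hot spots, and one ellipsoid of elevated uptake
    per lesion. The truth mask marks exactly the lesion voxels.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    sx, sy, sz = config.voxel_spacing_mm
    hu = config.tissue_hu_means

    body = _body_mask(config)

    # --- CT compartments -------------------------------------------------
    nx, ny, nz = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ax, ay = config.body_axes_mm
    x = (np.arange(nx)[:, None, None] - cx) * sx
    y = (np.arange(ny)[None, :, None] - cy) * sy
    r2 = (x / ax) ** 2 + (y / ay) ** 2
    adipose = body & (r2 > 0.55)  # outer subcutaneous shell
    # bone: spine-like column, posterior of center
    spine = _ellipsoid_mask(
        shape,
        (cx, cy + 0.45 * ay / sy, (nz - 1) / 2.0),
        (9.0 / sx, 9.0 / sy, nz),  # runs the full z extent
    ) & body
    lean = body & ~adipose & ~spine

    ct = np.full(shape, hu["air"], dtype=np.float64)
    ct[adipose] = hu["adipose"]
    ct[lean] = hu["lean"]
    ct[spine] = hu["bone"]
    ct += rng.normal(0.0, config.ct_noise_sd_hu, size=shape)
    ct = np.clip(ct, -1000.0, 1500.0)

    # --- SUV background and hot spots ------------------------------------
    suv = np.zeros(shape, dtype=np.float64)
    suv[body] = config.background_suv

    occupied: list[tuple[np.ndarray, float]] = []
    hotspot_specs = [(8.0, config.hotspot_suv)] * config.n_hotspots
    hotspots = _place_blobs(rng, config, hotspot_specs, occupied, "hotspot")
    for center_vox, radius_mm, uptake in hotspots:
        m = _ellipsoid_mask(shape, center_vox, (radius_mm / sx, radius_mm / sy, radius_mm / sz))
        suv[m] = uptake

    # --- lesions ----------------------------------------------------------
    if config.lesion_specs is not None:
        specs = [tuple(s) for s in config.lesion_specs]
    else:
        specs = [
            (
                rng.uniform(*config.lesion_radius_range_mm),
                rng.uniform(*config.lesion_suv_range),
            )
            for _ in range(config.n_lesions)
        ]
    placed = _place_blobs(rng, config, specs, occupied, "lesion")

    truth = np.zeros(shape, dtype=np.uint8)
    catalog = []
    for center_vox, radius_mm, uptake in placed:
        m = _ellipsoid_mask(shape, center_vox, (radius_mm / sx, radius_mm / sy, radius_mm / sz))
        suv[m] = uptake
        truth[m] = 1
        catalog.append(
            (tuple(int(round(c)) for c in center_vox), float(radius_mm), float(uptake))
        )

    suv += rng.normal(0.0, config.noise_sd, size=shape)
    suv[~body] = np.abs(rng.normal(0.0, config.noise_sd / 5.0, size=shape))[~body]
    suv = np.clip(suv, 0.0, None)

    spacing = tuple(config.voxel_spacing_mm)
    return PhantomSample(
        ct=VolumeGrid(ct, spacing),
        suv=VolumeGrid(suv, spacing),
        truth=VolumeGrid(truth, spacing),
        lesion_catalog=catalog,
    )


def lesion_truth_volumes_ml(sample: PhantomSample) -> list[float]:
    """Per-component lesion volumes in ml (27-connected components)."""
    labels = cc_label(sample.truth.values > 0, connectivity=3)
    vox_ml = sample.truth.voxel_volume_ml
    return [
        float(np.count_nonzero(labels == k) * vox_ml)
        for k in range(1, labels.max() + 1)
    ]


def hard_case_config(seed: int = 0, **overrides) -> PhantomConfig:
    """A phantom preset stressing the cases the prior is meant to rescue.

    Includes a sub-1 ml lesion (5 mm radius, ~0.5 ml) and a lesion whose
    uptake is barely above the soft-tissue background (SUV 1.6 over a
    background of 1.0), alongside one ordinary lesion.
    """
    defaults = dict(
        lesion_specs=[(9.0, 4.0), (5.0, 3.0), (8.0, 1.6)],
        background_suv=1.0,
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


def write_phantom(sample: PhantomSample, out_dir) -> None:
    """Write ct/suv/truth NIfTI volumes and a JSON lesion catalog."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_nifti(sample.ct, out / "ct.nii.gz")
    save_nifti(sample.suv, out / "suv.nii.gz")
    save_nifti(sample.truth, out / "truth.nii.gz")
    catalog = [
        {"centroid_voxel": list(c), "radius_mm": r, "mean_suv": s}
        for c, r, s in sample.lesion_catalog
    ]
    (out / "lesions.json").write_text(json.dumps(catalog, indent=2))
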