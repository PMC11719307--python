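"""Volume container and NIfTI I/O.

A :class:`VolumeGrid` is a 3D scalar field with voxel spacing and origin.
Array axes follow the (x: left-right, y: anterior-posterior,
z: inferior-superior) convention, so ``values[i, j, k]`` addresses the
voxel at physical position ``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "load_nifti", "save_nifti"]


@dataclass
class VolumeGrid:
    """A 3D scalar field on a regular anisotropic grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values (HU, SUV, or binary labels).
    spacing_mm : tuple of 3 floats
        Physical voxel edge lengths along x, y, z in millimetres.
    origin_mm : tuple of 3 floats
        Physical position of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {self.values.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be three positive lengths, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        """A copy of this grid carrying new voxel values (same geometry)."""
        return replace(self, values=np.asarray(values))

    def same_grid_as(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
        )

    def require_same_grid(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.same_grid_as(other):
            raise ValueError(
                f"grid mismatch for {what}: {self.shape}@{self.spacing_mm} vs "
                f"{other.shape}@{other.spacing_mm}"
            )

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff


def load_nifti(path) -> VolumeGrid:
    """Load a NIfTI volume as a :class:`VolumeGrid`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return VolumeGrid(data, spacing, origin)


def save_nifti(vol: VolumeGrid, path) -> None:
    """Write a :class:`VolumeGrid` to NIfTI, preserving spacing and origin."""
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
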