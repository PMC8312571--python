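"""Minimal 3D volume container with physical voxel spacing.

Arrays are indexed ``(i, j, k)`` with ``k`` the through-plane (slice) axis;
``spacing`` is the voxel size in mm along each axis in the same order. NIfTI
round-trips go through nibabel with a diagonal affine built from the spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "load_nifti", "save_nifti"]


@dataclass
class VolumeImage:
    """A 3D scalar grid (intensities or a binary label map) plus voxel spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def volume_ml(self) -> float:
        """Volume of the nonzero region in millilitres (1 mL = 1000 mm^3)."""
        return float(np.count_nonzero(self.data) * self.voxel_volume_mm3 / 1000.0)


def load_nifti(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return VolumeImage(np.asanyarray(img.dataobj), tuple(float(z) for z in zooms))


def save_nifti(vol: VolumeImage, path: str | Path) -> None:
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
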