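"""Grid resampling, intensity normalization and gray-level discretization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from ..volume import VolumeImage

__all__ = [
    "resample_to_grid",
    "normalize_intensities",
    "discretize_fixed_bin_width",
    "DiscretizedImage",
]


def _to_sitk(vol: VolumeImage) -> sitk.Image:
    # SimpleITK arrays are (z, y, x); our convention is (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T).astype(np.float64))
    img.SetSpacing(vol.spacing)
    return img


def resample_to_grid(
    image: VolumeImage,
    masks: dict[str, VolumeImage] | None,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 6.0),
) -> tuple[VolumeImage, dict[str, VolumeImage]]:
    """Resample image (linear) and masks (nearest-neighbour) to a new spacing.

    The output grid covers the same physical extent to within one voxel:
    ``new_size = round(old_size * old_spacing / new_spacing)``.
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if any(n < 2 for n in image.shape):
        raise ValueError(f"degenerate input axis in shape {image.shape}")
    target_spacing = tuple(float(s) for s in target_spacing)
    if target_spacing == image.spacing:
        return image, dict(masks or {})

    size = [
        max(int(round(n * s / t)), 1)
        for n, s, t in zip(image.shape, image.spacing, target_spacing)
    ]

    def _resample(vol: VolumeImage, interp) -> VolumeImage:
        src = _to_sitk(vol)
        res = sitk.Resample(
            src,
            size,
            sitk.Transform(),
            interp,
            src.GetOrigin(),
            target_spacing,
            src.GetDirection(),
            0.0,
            sitk.sitkFloat64,
        )
        return VolumeImage(sitk.GetArrayFromImage(res).T.copy(), target_spacing)

    out_img = _resample(image, sitk.sitkLinear)
    out_masks = {}
    for name, m in (masks or {}).items():
        r = _resample(VolumeImage(m.data.astype(np.float64), m.spacing), sitk.sitkNearestNeighbor)
        out_masks[name] = VolumeImage(r.data > 0.5, target_spacing)
    return out_img, out_masks


def normalize_intensities(
    image: VolumeImage, mask: VolumeImage, scale: float = 100.0
) -> VolumeImage:
    """Z-score intensities against in-mask mean/SD, then multiply by ``scale``.

    The affine map is applied to the whole volume (filters need smooth data
    outside the mask too); in-mask voxels end up with mean 0 and SD ``scale``.
    """
    m = mask.as_bool()
    if not m.any():
        raise ValueError("mask is empty")
    vals = image.data[m]
    mu, sd = float(vals.mean()), float(vals.std())
    if sd == 0:
        raise ValueError("zero in-mask intensity variance")
    return VolumeImage((image.data - mu) / sd * scale, image.spacing)


@dataclass
class DiscretizedImage:
    """Integer gray-level grid: levels 1..n_levels inside the mask, 0 outside."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_width: float

    @property
    def spacing(self):  # filled by caller when known
        return getattr(self, "_spacing", (1.0, 1.0, 1.0))


def discretize_fixed_bin_width(
    image: VolumeImage, mask: VolumeImage, bin_width: float = 5.0
) -> DiscretizedImage:
    """Fixed-bin-width quantization: ``level(x) = floor(x/w) - floor(min/w) + 1``.

    The reference minimum is the in-mask minimum, so levels start at 1 and
    the map is monotone in intensity.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    m = mask.as_bool()
    if not m.any():
        raise ValueError("mask is empty")
    w = float(bin_width)
    base = np.floor(image.data[m].min() / w)
    lev = np.zeros(image.shape, dtype=np.int32)
    lev[m] = (np.floor(image.data[m] / w) - base + 1).astype(np.int32)
    d = DiscretizedImage(lev, m, int(lev.max()), w)
    d._spacing = image.spacing
    return d
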