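"""Slice-wise image filters: Laplacian of Gaussian, wavelet sub-bands, LBP.

All filters act within axial slices (the through-plane resolution is far
coarser than in-plane, so 3D filtering would mix anatomy across ~6 mm).
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy import ndimage
from skimage.feature import local_binary_pattern

from ..volume import VolumeImage

__all__ = ["log_filter", "wavelet_subbands", "lbp2d", "filter_image"]

WAVELET_BANDS = ("LL", "LH", "HL", "HH")


def log_filter(image: VolumeImage, sigma_mm: float) -> VolumeImage:
    """Per-slice 2D Laplacian-of-Gaussian; sigma given in mm.

    Sigma is converted to voxels with the in-plane spacing (both in-plane
    spacings must agree); the Gaussian kernel is truncated at 4 sigma.
    """
    if sigma_mm <= 0:
        raise ValueError(f"sigma must be positive, got {sigma_mm}")
    sx, sy, _ = image.spacing
    if not np.isclose(sx, sy):
        raise ValueError("anisotropic in-plane spacing not supported for LoG")
    sigma_vox = sigma_mm / sx
    # DC correction: the truncated kernel's sum is not exactly zero, so a
    # constant image would not map to zero; subtract the residual gain.
    m = 2 * int(np.ceil(4.0 * sigma_vox)) + 5
    dc = ndimage.gaussian_laplace(
        np.ones((m, m)), sigma=sigma_vox, truncate=4.0, mode="nearest"
    )[m // 2, m // 2]
    out = np.empty_like(image.data, dtype=float)
    for k in range(image.shape[2]):
        sl = image.data[:, :, k].astype(float)
        out[:, :, k] = (
            ndimage.gaussian_laplace(sl, sigma=sigma_vox, truncate=4.0, mode="nearest")
            - dc * sl
        )
    return VolumeImage(out, image.spacing)


def _wavelet_kernels(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(wavelet)
    return np.asarray(w.dec_lo, dtype=float), np.asarray(w.dec_hi, dtype=float)


def wavelet_subbands(image: VolumeImage, wavelet: str = "coif1") -> dict[str, VolumeImage]:
    """Undecimated single-level 2D wavelet decomposition per slice.

    Separable convolution with the decomposition low/high-pass filters along
    the two in-plane axes (reflect boundary); outputs keep the input grid so
    the extraction mask applies unchanged. Band naming: first letter = filter
    along axis 0 (rows), second = axis 1 (columns); e.g. ``LH`` is low-pass
    on rows, high-pass on columns.
    """
    lo, hi = _wavelet_kernels(wavelet)
    taps = {"L": lo, "H": hi}
    out = {}
    for band in WAVELET_BANDS:
        res = np.empty_like(image.data, dtype=float)
        for k in range(image.shape[2]):
            sl = image.data[:, :, k].astype(float)
            sl = ndimage.convolve1d(sl, taps[band[0]], axis=0, mode="reflect")
            sl = ndimage.convolve1d(sl, taps[band[1]], axis=1, mode="reflect")
            res[:, :, k] = sl
        out[band] = VolumeImage(res, image.spacing)
    return out


def lbp2d(image: VolumeImage, radius: int = 1, n_points: int = 8) -> VolumeImage:
    """Per-slice rotation-invariant uniform local-binary-pattern code image."""
    out = np.empty_like(image.data, dtype=float)
    with warnings.catch_warnings():
        # float input is intentional (codes of the normalized image)
        warnings.simplefilter("ignore", UserWarning)
        for k in range(image.shape[2]):
            out[:, :, k] = local_binary_pattern(
                image.data[:, :, k].astype(float), n_points, radius, method="uniform"
            )
    return VolumeImage(out, image.spacing)


def filter_image(image: VolumeImage, kind: str, **params) -> VolumeImage | dict[str, VolumeImage]:
    """Dispatch: ``log`` (needs sigma_mm), ``wavelet`` (dict of bands), ``lbp2d``."""
    if kind == "log":
        return log_filter(image, params["sigma_mm"])
    if kind == "wavelet":
        return wavelet_subbands(image, params.get("wavelet", "coif1"))
    if kind == "lbp2d":
        return lbp2d(image, params.get("radius", 1), params.get("n_points", 8))
    raise ValueError(f"unknown filter kind {kind!r}")
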