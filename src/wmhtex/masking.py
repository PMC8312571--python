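"""Normal-appearing-brain masks and the transformed WMH burden outcome.

The extraction region for radiomics is the brain parenchyma outside visible
lesions: total brain minus ventricles minus white-matter hyperintensities
(WMH), cleaned with a slice-wise 3x3 morphological opening to drop stray
voxels. The regression outcome is the WMH volume fraction (WMH / brain),
Box-Cox transformed because the raw fraction is strongly right-skewed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from .volume import VolumeImage

__all__ = [
    "MaskSet",
    "BurdenRecord",
    "normal_appearing_mask",
    "wmh_fraction",
    "boxcox_transform",
    "cohort_burden",
]

_OPENING_KERNEL = np.ones((3, 3), dtype=bool)


@dataclass
class MaskSet:
    """Aligned binary volumes: total brain, ventricles and WMH on one grid."""

    brain: VolumeImage
    ventricles: VolumeImage
    wmh: VolumeImage

    def __post_init__(self) -> None:
        shapes = {self.brain.shape, self.ventricles.shape, self.wmh.shape}
        if len(shapes) != 1:
            raise ValueError(f"mask shapes differ: {sorted(shapes)}")
        spacings = {self.brain.spacing, self.ventricles.spacing, self.wmh.spacing}
        if len(spacings) != 1:
            raise ValueError(f"mask spacings differ: {sorted(spacings)}")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.brain.spacing


@dataclass
class BurdenRecord:
    """Per-subject WMH burden: volumes, fraction and its Box-Cox transform."""

    wmh_ml: float
    brain_ml: float
    fraction: float
    burden: float
    lam: float
    shift: float


def normal_appearing_mask(masks: MaskSet) -> VolumeImage:
    """Brain minus ventricles minus WMH, opened slice-wise with a 3x3 kernel.

    The opening is 2D (per axial slice): with ~6 mm slices a 3D 3x3x3 kernel
    would erode entire slabs, so the planar kernel is the meaningful reading.
    """
    raw = masks.brain.as_bool() & ~masks.ventricles.as_bool() & ~masks.wmh.as_bool()
    out = np.zeros_like(raw)
    for k in range(raw.shape[2]):
        out[:, :, k] = ndimage.binary_opening(raw[:, :, k], structure=_OPENING_KERNEL)
    return VolumeImage(out, masks.spacing)


def wmh_fraction(masks: MaskSet) -> tuple[float, float, float]:
    """Return ``(fraction, wmh_ml, brain_ml)``.

    fraction = WMH voxel count / brain voxel count (dimensionless ratio; the
    percentage is presentation scaling only). Volumes in mL via voxel size.
    """
    n_brain = int(np.count_nonzero(masks.brain.data))
    if n_brain == 0:
        raise ValueError("brain mask is empty")
    n_wmh = int(np.count_nonzero(masks.wmh.data))
    vox_ml = masks.brain.voxel_volume_mm3 / 1000.0
    return n_wmh / n_brain, n_wmh * vox_ml, n_brain * vox_ml


def boxcox_transform(
    values: np.ndarray, lam: float | None = None, shift: str | float = "auto"
) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform ``y = (x^lam - 1)/lam`` (``ln x`` at ``lam = 0``).

    Parameters
    ----------
    values : positive reals (zeros allowed when ``shift='auto'``).
    lam : fixed exponent, or ``None`` to fit by profile maximum likelihood
        (bracketed search over ``[-3, 3]``).
    shift : offset added before transforming. ``'auto'`` shifts by half the
        smallest positive value when zeros are present, else 0.

    Returns ``(transformed, lam, shift)``.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if shift == "auto":
        if np.any(x < 0):
            raise ValueError("negative values; supply an explicit shift")
        if np.any(x == 0):
            pos = x[x > 0]
            if pos.size == 0:
                raise ValueError("all values zero; Box-Cox undefined")
            shift_v = float(pos.min() / 2.0)
        else:
            shift_v = 0.0
    else:
        shift_v = float(shift)
    xs = x + shift_v
    bad = np.nonzero(xs <= 0)[0]
    if bad.size:
        raise ValueError(f"nonpositive value after shift at index {bad[0]}")
    if lam is None:
        lam = float(stats.boxcox_normmax(xs, brack=(-3.0, 3.0), method="mle"))
    y = special.boxcox(xs, float(lam))
    return y, float(lam), shift_v


def cohort_burden(volumes: pd.DataFrame, lam: float | None = None) -> pd.DataFrame:
    """Build per-subject burden records for a cohort.

    ``volumes`` needs columns ``subject_id, wmh_ml, brain_ml``. The Box-Cox
    exponent is fitted once on the whole cohort's fractions (single outcome
    scale for all subjects). Returns columns
    ``subject_id, wmh_ml, brain_ml, fraction, burden, lambda, shift``.
    """
    df = volumes.copy()
    if (df["brain_ml"] <= 0).any():
        raise ValueError("brain volumes must be positive")
    frac = (df["wmh_ml"] / df["brain_ml"]).to_numpy(dtype=float)
    if np.any(frac < 0) or np.any(frac >= 1):
        raise ValueError("fractions must lie in [0, 1)")
    burden, lam_fit, shift = boxcox_transform(frac, lam=lam)
    out = pd.DataFrame(
        {
            "subject_id": df["subject_id"].to_numpy(),
            "wmh_ml": df["wmh_ml"].to_numpy(dtype=float),
            "brain_ml": df["brain_ml"].to_numpy(dtype=float),
            "fraction": frac,
            "burden": burden,
        }
    )
    out["lambda"] = lam_fit
    out["shift"] = shift
    return out
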