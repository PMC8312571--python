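"""End-to-end radiomic feature extraction from the normal-appearing brain.

Pipeline per subject: resample to the extraction grid -> build the
normal-appearing mask -> normalize intensities inside it -> for every
configured filter, discretize (fixed bin width) and compute first-order plus
all five texture families; shape features come once from the mask itself.
Feature names follow ``<filter>_<class>_<feature>``, e.g.
``log-sigma-2_gldm_GrayLevelNonUniformity`` or ``original_shape_Sphericity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..masking import MaskSet, normal_appearing_mask
from ..volume import VolumeImage
from . import filters as _filters
from .features import first_order_features, shape_features, texture_features
from .matrices import FAMILIES, build_texture_matrix
from .preprocess import discretize_fixed_bin_width, normalize_intensities, resample_to_grid

__all__ = ["ExtractionConfig", "extract_features", "extract_cohort", "feature_dictionary"]

DEFAULT_FILTERS = (
    "original",
    "log-sigma-1",
    "log-sigma-2",
    "log-sigma-3",
    "wavelet-LL",
    "wavelet-LH",
    "wavelet-HL",
    "wavelet-HH",
    "lbp-2D",
)


@dataclass
class ExtractionConfig:
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 6.0)
    bin_width: float = 5.0
    normalization_scale: float = 100.0
    filters: tuple[str, ...] = DEFAULT_FILTERS
    texture_families: tuple[str, ...] = FAMILIES
    first_order: bool = True
    shape: bool = True
    wavelet: str = "coif1"
    gldm_alpha: int = 0

    def validate(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")
        for f in self.filters:
            if f != "original" and not f.startswith(("log-sigma-", "wavelet-", "lbp")):
                raise ValueError(f"unknown filter {f!r}")
        unknown = set(self.texture_families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown texture families {sorted(unknown)}")


def _filtered_images(
    image: VolumeImage, config: ExtractionConfig
) -> dict[str, VolumeImage]:
    out: dict[str, VolumeImage] = {}
    wavelet_cache = None
    for name in config.filters:
        if name == "original":
            out[name] = image
        elif name.startswith("log-sigma-"):
            out[name] = _filters.log_filter(image, float(name.rsplit("-", 1)[1]))
        elif name.startswith("wavelet-"):
            if wavelet_cache is None:
                wavelet_cache = _filters.wavelet_subbands(image, config.wavelet)
            out[name] = wavelet_cache[name.split("-", 1)[1]]
        elif name.startswith("lbp"):
            out[name] = _filters.lbp2d(image)
    return out


def extract_features(
    image: VolumeImage,
    masks: MaskSet,
    config: ExtractionConfig | None = None,
) -> dict[str, float]:
    """Extract the full configured feature vector for one subject."""
    config = config or ExtractionConfig()
    config.validate()
    image, rmasks = resample_to_grid(
        image,
        {"brain": masks.brain, "ventricles": masks.ventricles, "wmh": masks.wmh},
        config.target_spacing,
    )
    masks = MaskSet(rmasks["brain"], rmasks["ventricles"], rmasks["wmh"])
    nawm = normal_appearing_mask(masks)
    if not nawm.data.any():
        raise ValueError("normal-appearing mask is empty after opening")
    image = normalize_intensities(image, nawm, config.normalization_scale)

    out: dict[str, float] = {}
    if config.shape:
        for k, v in shape_features(nawm).items():
            out[f"original_shape_{k}"] = v
    for fname, fimg in _filtered_images(image, config).items():
        d = discretize_fixed_bin_width(fimg, nawm, config.bin_width)
        if config.first_order:
            for k, v in first_order_features(fimg, nawm, d).items():
                out[f"{fname}_firstorder_{k}"] = v
        for family in config.texture_families:
            m = build_texture_matrix(d, family, alpha=config.gldm_alpha)
            for k, v in texture_features(m).items():
                out[f"{fname}_{family}_{k}"] = v
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features: {bad[:5]}")
    return out


def extract_cohort(
    subjects: list[tuple[str, VolumeImage, MaskSet]],
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Wide feature table, one row per subject (column 0 = subject_id)."""
    rows = []
    for sid, image, masks in subjects:
        try:
            feats = extract_features(image, masks, config)
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for subject {sid}") from exc
        rows.append({"subject_id": sid, **feats})
    return pd.DataFrame(rows)


def feature_dictionary(columns: list[str]) -> dict[str, dict]:
    """Per-feature metadata parsed from ``<filter>_<class>_<feature>`` names."""
    out = {}
    for c in columns:
        parts = c.split("_", 2)
        if len(parts) != 3:
            continue
        filt, cls, feat = parts
        out[c] = {
            "filter": filt,
            "class": cls,
            "feature": feat,
            "kind": "shape" if cls == "shape" else "intensity",
        }
    return out
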