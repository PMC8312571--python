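"""Feature formulas: texture-matrix, first-order and shape descriptors.

Formulas follow the standardized radiomics definitions (IBSI-style naming,
e.g. GLRLM ShortRunLowGrayLevelEmphasis = (1/N_r) * sum P(i,j)/(i^2 j^2)).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy import stats as sstats
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from ..volume import VolumeImage
from .matrices import TextureMatrix
from .preprocess import DiscretizedImage

__all__ = ["texture_features", "first_order_features", "shape_features"]

_EPS = np.finfo(float).eps


def _glcm_features(P: np.ndarray) -> dict[str, float]:
    Ns = P.sum()
    if Ns == 0:
        raise ValueError("empty GLCM")
    p = P / Ns
    ng = p.shape[0]
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((p * i).sum())
    muy = float((p * j).sum())
    sigx = np.sqrt(((i.ravel() - mux) ** 2 * px).sum())
    sigy = np.sqrt(((j.ravel() - muy) ** 2 * py).sum())
    # difference |i-j| = k (k = 0..ng-1) and sum i+j = k (k = 2..2ng) marginals
    kd = np.abs(i - j)
    pd_ = np.array([p[kd == k].sum() for k in range(ng)])
    ks = i + j
    ps = np.array([p[ks == k].sum() for k in range(2, 2 * ng + 1)])
    kd_vals = np.arange(ng)
    ks_vals = np.arange(2, 2 * ng + 1)
    da = float((pd_ * kd_vals).sum())
    hx = -float((px[px > 0] * np.log2(px[px > 0])).sum())
    hy = -float((py[py > 0] * np.log2(py[py > 0])).sum())
    hxy = -float((p[p > 0] * np.log2(p[p > 0])).sum())
    pxy = px[:, None] * py[None, :]
    m = p > 0
    hxy1 = -float((p[m] * np.log2(pxy[m] + _EPS)).sum())
    m2 = pxy > 0
    hxy2 = -float((pxy[m2] * np.log2(pxy[m2])).sum())
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = np.sqrt(max(1 - np.exp(-2 * (hxy2 - hxy)), 0.0))
    offdiag = kd > 0
    out = {
        "Autocorrelation": float((p * i * j).sum()),
        "JointAverage": mux,
        "ClusterProminence": float((p * (i + j - mux - muy) ** 4).sum()),
        "ClusterShade": float((p * (i + j - mux - muy) ** 3).sum()),
        "ClusterTendency": float((p * (i + j - mux - muy) ** 2).sum()),
        "Contrast": float((p * (i - j) ** 2).sum()),
        "Correlation": (
            float(((p * i * j).sum() - mux * muy) / (sigx * sigy))
            if sigx > 0 and sigy > 0
            else 1.0
        ),
        "DifferenceAverage": da,
        "DifferenceEntropy": -float(
            (pd_[pd_ > 0] * np.log2(pd_[pd_ > 0])).sum()
        ),
        "DifferenceVariance": float((pd_ * (kd_vals - da) ** 2).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": float(imc2),
        "Idm": float((p / (1.0 + (i - j) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((i - j) / ng) ** 2)).sum()),
        "Id": float((p / (1.0 + kd)).sum()),
        "Idn": float((p / (1.0 + kd / ng)).sum()),
        "InverseVariance": float((p[offdiag] / kd[offdiag] ** 2).sum()),
        "MaximumProbability": float(p.max()),
        "SumAverage": float((ps * ks_vals).sum()),
        "SumEntropy": -float((ps[ps > 0] * np.log2(ps[ps > 0])).sum()),
        "SumSquares": float((p * (i - mux) ** 2).sum()),
    }
    return out


def _run_zone_features(P: np.ndarray, n_vox_weight: float, kind: str) -> dict[str, float]:
    """Shared GLRLM/GLSZM formula set; ``kind`` picks the naming."""
    Nr = P.sum()
    if Nr == 0:
        raise ValueError("empty matrix")
    p = P / Nr
    ng, nl = p.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nl + 1)[None, :]
    pg = p.sum(axis=1)  # gray-level marginal
    pl = p.sum(axis=0)  # run-length / zone-size marginal
    mu_i = float((pg * np.arange(1, ng + 1)).sum())
    mu_j = float((pl * np.arange(1, nl + 1)).sum())
    ent = -float((p[p > 0] * np.log2(p[p > 0])).sum())
    names = {
        "glrlm": (
            "ShortRunEmphasis",
            "LongRunEmphasis",
            "RunLengthNonUniformity",
            "RunLengthNonUniformityNormalized",
            "RunPercentage",
            "RunVariance",
            "RunEntropy",
            "LowGrayLevelRunEmphasis",
            "HighGrayLevelRunEmphasis",
            "ShortRunLowGrayLevelEmphasis",
            "ShortRunHighGrayLevelEmphasis",
            "LongRunLowGrayLevelEmphasis",
            "LongRunHighGrayLevelEmphasis",
        ),
        "glszm": (
            "SmallAreaEmphasis",
            "LargeAreaEmphasis",
            "SizeZoneNonUniformity",
            "SizeZoneNonUniformityNormalized",
            "ZonePercentage",
            "ZoneVariance",
            "ZoneEntropy",
            "LowGrayLevelZoneEmphasis",
            "HighGrayLevelZoneEmphasis",
            "SmallAreaLowGrayLevelEmphasis",
            "SmallAreaHighGrayLevelEmphasis",
            "LargeAreaLowGrayLevelEmphasis",
            "LargeAreaHighGrayLevelEmphasis",
        ),
    }[kind]
    out = {
        names[0]: float((p / j**2).sum()),
        names[1]: float((p * j**2).sum()),
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / Nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        names[2]: float((P.sum(axis=0) ** 2).sum() / Nr),
        names[3]: float((pl**2).sum()),
        names[4]: float(Nr / n_vox_weight),
        "GrayLevelVariance": float((pg * (np.arange(1, ng + 1) - mu_i) ** 2).sum()),
        names[5]: float((pl * (np.arange(1, nl + 1) - mu_j) ** 2).sum()),
        names[6]: ent,
        names[7]: float((p / i**2).sum()),
        names[8]: float((p * i**2).sum()),
        names[9]: float((p / (i**2 * j**2)).sum()),
        names[10]: float((p * i**2 / j**2).sum()),
        names[11]: float((p * j**2 / i**2).sum()),
        names[12]: float((p * i**2 * j**2).sum()),
    }
    return out


def _gldm_features(P: np.ndarray) -> dict[str, float]:
    Nz = P.sum()
    if Nz == 0:
        raise ValueError("empty GLDM")
    p = P / Nz
    ng, nd = p.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nd + 1)[None, :]
    pg = p.sum(axis=1)
    pdep = p.sum(axis=0)
    mu_i = float((pg * np.arange(1, ng + 1)).sum())
    mu_j = float((pdep * np.arange(1, nd + 1)).sum())
    return {
        "SmallDependenceEmphasis": float((p / j**2).sum()),
        "LargeDependenceEmphasis": float((p * j**2).sum()),
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / Nz),
        "DependenceNonUniformity": float((P.sum(axis=0) ** 2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((pdep**2).sum()),
        "GrayLevelVariance": float((pg * (np.arange(1, ng + 1) - mu_i) ** 2).sum()),
        "DependenceVariance": float((pdep * (np.arange(1, nd + 1) - mu_j) ** 2).sum()),
        "DependenceEntropy": -float((p[p > 0] * np.log2(p[p > 0])).sum()),
        "LowGrayLevelEmphasis": float((p / i**2).sum()),
        "HighGrayLevelEmphasis": float((p * i**2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (i**2 * j**2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * i**2 / j**2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * j**2 / i**2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * i**2 * j**2).sum()),
    }


def _ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    Np = n_i.sum()
    if Np == 0:
        raise ValueError("empty NGTDM")
    p = n_i / Np
    lev = np.arange(1, len(n_i) + 1, dtype=float)
    act = p > 0
    ngp = int(act.sum())
    iv, jv = np.meshgrid(lev[act], lev[act], indexing="ij")
    pi, pj = np.meshgrid(p[act], p[act], indexing="ij")
    si = s_i[act]
    sum_ps = float((p * s_i).sum())
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6
    if ngp > 1:
        contrast = float(
            (pi * pj * (iv - jv) ** 2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / Np)
        )
        denom = float(np.abs(iv * pi - jv * pj).sum())
        busyness = sum_ps / denom if denom > 0 else 0.0
        complexity = float(
            (np.abs(iv - jv) * (pi * si[:, None] + pj * si[None, :]) / (pi + pj)).sum()
            / Np
        )
        s_sum = float(s_i.sum())
        strength = float(((pi + pj) * (iv - jv) ** 2).sum() / s_sum) if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def texture_features(m: TextureMatrix) -> dict[str, float]:
    """Full standardized feature set for one texture matrix."""
    if m.family == "glcm":
        return _glcm_features(m.matrix)
    if m.family == "glrlm":
        # voxel weight = total run-length-weighted voxels (4 merged directions)
        nl = m.matrix.shape[1]
        weight = float((m.matrix * np.arange(1, nl + 1)[None, :]).sum())
        return _run_zone_features(m.matrix, weight, "glrlm")
    if m.family == "glszm":
        return _run_zone_features(m.matrix, float(m.n_voxels), "glszm")
    if m.family == "gldm":
        return _gldm_features(m.matrix)
    if m.family == "ngtdm":
        return _ngtdm_features(m.extras["n_i"], m.extras["s_i"])
    raise ValueError(f"unknown family {m.family!r}")


def first_order_features(
    image: VolumeImage, mask: VolumeImage, d: DiscretizedImage | None = None
) -> dict[str, float]:
    """Histogram statistics of in-mask intensities (percentiles: linear interp)."""
    m = mask.as_bool()
    if not m.any():
        raise ValueError("empty mask")
    x = image.data[m].astype(float)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    var = float(x.var())
    mu = float(x.mean())
    degenerate = np.sqrt(var) <= 1e-10 * max(1.0, abs(mu))
    out = {
        "Mean": mu,
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "InterquartileRange": float(p75 - p25),
        "Variance": var,
        "Skewness": float(sstats.skew(x)) if not degenerate else 0.0,
        "Kurtosis": float(sstats.kurtosis(x, fisher=False)) if not degenerate else 0.0,
        "MeanAbsoluteDeviation": float(np.abs(x - mu).mean()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Energy": float((x**2).sum()),
        "TotalEnergy": float((x**2).sum() * image.voxel_volume_mm3),
    }
    q = x[(x >= p10) & (x <= p90)]
    out["RobustMeanAbsoluteDeviation"] = (
        float(np.abs(q - q.mean()).mean()) if q.size else 0.0
    )
    if d is not None:
        counts = np.bincount(d.levels[d.mask], minlength=d.n_levels + 1)[1:]
        p = counts / counts.sum()
        p = p[p > 0]
        out["Entropy"] = -float((p * np.log2(p)).sum())
        out["Uniformity"] = float((p**2).sum())
    return out


def _max_diameter(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    pts = np.unique(np.round(points, 6), axis=0)
    if len(pts) > 8:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (collinear) projections
            pass
    if len(pts) < 2:
        return 0.0
    return float(pdist(pts).max())


def shape_features(mask: VolumeImage, spacing: tuple | None = None) -> dict[str, float]:
    """Mesh- and moment-based shape descriptors of a binary region.

    A triangular surface mesh is extracted at the 0.5 iso-level on the
    physical grid (mask padded so boundary regions close). Sphericity =
    (36 pi V^2)^(1/3) / A; axis lengths are 4 * sqrt(eigenvalues) of the
    physical voxel-coordinate covariance; Maximum2DDiameter{Slice,Column,Row}
    are the largest pairwise mesh-vertex distances in the axial (drop axis 2),
    coronal (drop axis 1) and sagittal (drop axis 0) projections.
    """
    sp = tuple(spacing or mask.spacing)
    m = mask.as_bool()
    if not m.any():
        raise ValueError("empty mask")
    padded = np.pad(m, 2).astype(float)
    # light anti-aliasing before meshing: a staircase mesh overestimates the
    # surface of smooth objects by ~8%; one-voxel smoothing removes most of
    # the bias without eroding desk-scale regions
    field = ndimage.gaussian_filter(padded, sigma=1.0)
    if field.max() <= 0.5:
        field = padded
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=sp)
    area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    vol = float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    coords = np.argwhere(m).astype(float) * np.asarray(sp)
    n = len(coords)
    evals = np.zeros(3)
    if n > 1:
        evals = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        evals = np.clip(evals, 0, None)
    axes = 4.0 * np.sqrt(evals)
    out = {
        "MeshVolume": vol,
        "VoxelVolume": float(n * np.prod(sp)),
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / vol if vol > 0 else np.inf,
        "Sphericity": float((36 * np.pi * vol**2) ** (1 / 3) / area) if vol > 0 else 0.0,
        "MajorAxisLength": float(axes[0]),
        "MinorAxisLength": float(axes[1]),
        "LeastAxisLength": float(axes[2]),
        "Elongation": float(np.sqrt(evals[1] / evals[0])) if evals[0] > 0 else 1.0,
        "Flatness": float(np.sqrt(evals[2] / evals[0])) if evals[0] > 0 else 1.0,
        "Maximum3DDiameter": _max_diameter(verts),
        "Maximum2DDiameterSlice": _max_diameter(verts[:, :2]),
        "Maximum2DDiameterColumn": _max_diameter(verts[:, [0, 2]]),
        "Maximum2DDiameterRow": _max_diameter(verts[:, 1:]),
    }
    return out
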