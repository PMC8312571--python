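"""Synthetic cohort: clinical tables, WMH burdens, image phantoms and
planted-structure feature tables.

The real study population (an acute ischemic stroke cohort) is private, so
every downstream stage is exercised on a calibrated stand-in. Clinical
marginals default to the published cohort description: age 62.8 (SD 15.0)
years truncated to [18, 100], 42.0% female, hypertension 67.9%, diabetes
16.5%, atrial fibrillation 14.3%, coronary artery disease 18.5%, smoking
32.0%; WMH volume lognormal with median 4.2 mL and IQR 1.4-11.2 mL
(sigma_log = ln(11.2/1.4) / (2 * 0.6745)). Covariate effects on burden and
on image texture default to zero: the defaults reproduce marginals only, and
planted dependencies are explicit, seeded choices carried in the config and
returned as ground truth so recovery can be asserted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import VolumeImage

__all__ = [
    "BINARY_COLUMNS",
    "CLINICAL_COLUMNS",
    "CohortConfig",
    "PhantomSpec",
    "GroundTruth",
    "generate_clinical_cohort",
    "generate_wmh_volumes",
    "synthesize_phantom",
    "generate_feature_table",
]

BINARY_COLUMNS = ("sex_female", "htn", "dm", "af", "cad", "smoking")
CLINICAL_COLUMNS = ("subject_id", "age") + BINARY_COLUMNS + ("nihss", "site")

#: sigma of log WMH volume matching the printed IQR of a lognormal:
#: (ln 11.2 - ln 1.4) / (2 * Phi^-1(0.75))
WMH_SIGMA_LOG = float(math.log(11.2 / 1.4) / (2 * stats.norm.ppf(0.75)))


@dataclass
class CohortConfig:
    """Marginal and dependence parameters of the simulated cohort."""

    n_subjects: int = 4163
    age_mean: float = 62.8
    age_sd: float = 15.0
    age_min: float = 18.0
    age_max: float = 100.0
    prevalences: dict = field(
        default_factory=lambda: {
            "sex_female": 0.420,
            "htn": 0.679,
            "dm": 0.165,
            "af": 0.143,
            "cad": 0.185,
            "smoking": 0.320,
        }
    )
    wmh_mu_log: float = math.log(4.2)
    wmh_sigma_log: float = WMH_SIGMA_LOG
    #: log-scale effect of each standardized covariate on WMH volume
    burden_coefs: dict = field(default_factory=dict)
    #: per-covariate texture-modulation amplitude used by the phantom
    texture_coefs: dict = field(default_factory=dict)
    brain_mean_ml: float = 1400.0
    brain_sd_ml: float = 130.0
    nihss_median: float = 3.0
    nihss_sigma_log: float = 0.9
    nihss_missing_rate: float = 0.463
    missing_rate: float = 0.0  # MCAR rate on binary covariates
    n_sites: int = 17
    seed: int = 0

    def validate(self) -> None:
        for name in ("age_mean", "age_sd", "wmh_mu_log", "wmh_sigma_log"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.age_sd <= 0:
            raise ValueError(f"age_sd must be positive, got {self.age_sd}")
        if self.wmh_sigma_log < 0:
            raise ValueError(f"wmh_sigma_log must be nonnegative, got {self.wmh_sigma_log}")
        if self.age_min <= 0 or self.age_max <= self.age_min:
            raise ValueError("age truncation bounds must satisfy 0 < age_min < age_max")
        for k, p in self.prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence[{k}] must lie in [0, 1], got {p}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        if self.n_subjects < 0 or self.n_sites < 1:
            raise ValueError("n_subjects must be >= 0 and n_sites >= 1")


@dataclass
class PhantomSpec:
    """Geometry and texture parameters of the image phantom.

    The default 96 x 96 x 24 grid at 1 x 1 x 6 mm matches the feature
    extraction grid while keeping a single phantom to ~0.9 MB in memory.
    """

    shape: tuple[int, int, int] = (96, 96, 24)
    spacing: tuple[float, float, float] = (1.0, 1.0, 6.0)
    brain_halfaxes_mm: tuple[float, float, float] = (42.0, 38.0, 60.0)
    ventricle_halfaxes_mm: tuple[float, float, float] = (7.0, 16.0, 20.0)
    ventricle_offset_mm: float = 9.0
    tissue_intensity: float = 100.0
    csf_intensity: float = 30.0
    wmh_intensity: float = 180.0
    noise_sd: float = 6.0
    patch_sigma_mm: float = 6.0
    patch_amplitude: float = 8.0

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing) or any(n < 4 for n in self.shape):
            raise ValueError("spacing must be positive and grid at least 4 voxels per axis")
        extent = [n * s / 2 for n, s in zip(self.shape, self.spacing)]
        if any(h >= e for h, e in zip(self.brain_halfaxes_mm, extent)):
            raise ValueError("brain ellipsoid does not fit inside the grid")
        if any(v >= b for v, b in zip(self.ventricle_halfaxes_mm, self.brain_halfaxes_mm)):
            raise ValueError("ventricles must fit inside the brain")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic feature table."""

    feature_names: list
    beta_true: np.ndarray
    rho_true: tuple
    informative_features: list
    clinical_loadings: np.ndarray
    feature_loadings: np.ndarray


def _site_labels(n: int, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    return np.array([f"site{j + 1:02d}" for j in rng.integers(0, n_sites, size=n)])


def generate_clinical_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a clinical table with the configured marginals.

    Age comes from a truncated normal; the binary risk factors are Bernoulli
    at the configured prevalences; NIHSS is a rounded lognormal with the
    configured median, missing completely at random at the configured rate.
    Deterministic for a fixed config (seed included).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    cols: dict = {"subject_id": [f"sub-{i + 1:05d}" for i in range(n)]}
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    cols["age"] = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    for name in BINARY_COLUMNS:
        p = config.prevalences.get(name, 0.0)
        vals = (rng.random(n) < p).astype(float)
        if config.missing_rate > 0:
            vals[rng.random(n) < config.missing_rate] = np.nan
        cols[name] = vals
    nihss = np.round(
        np.exp(rng.normal(math.log(config.nihss_median), config.nihss_sigma_log, size=n))
    )
    nihss[rng.random(n) < config.nihss_missing_rate] = np.nan
    cols["nihss"] = nihss
    cols["site"] = _site_labels(n, config.n_sites, rng)
    df = pd.DataFrame(cols, columns=list(CLINICAL_COLUMNS))
    if n == 0:  # keep dtypes sane for the empty schema
        df = df.astype({"age": float, "nihss": float})
    return df


def _standardized_covariates(clinical: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    z = {}
    z["age"] = (clinical["age"] - config.age_mean) / config.age_sd
    for name in BINARY_COLUMNS:
        p = config.prevalences.get(name, 0.0)
        scale = math.sqrt(p * (1 - p)) if 0 < p < 1 else 1.0
        z[name] = (clinical[name].fillna(p) - p) / scale
    return pd.DataFrame(z, index=clinical.index)


def generate_wmh_volumes(clinical: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Per-subject WMH and brain volumes (mL).

    log(WMH) = mu_log + sum_j coef_j * z_j + sigma_log * eps with z_j the
    standardized covariates, so with all coefficients zero the marginal is
    exactly lognormal(mu_log, sigma_log); sigma_log is the residual scale.
    """
    config.validate()
    if len(clinical) == 0:
        raise ValueError("clinical table is empty")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    n = len(clinical)
    z = _standardized_covariates(clinical, config)
    lin = np.zeros(n)
    for name, coef in config.burden_coefs.items():
        if name not in z.columns:
            raise KeyError(f"unknown covariate in burden_coefs: {name!r}")
        lin += coef * z[name].to_numpy()
    log_wmh = config.wmh_mu_log + lin + config.wmh_sigma_log * rng.standard_normal(n)
    brain = np.maximum(
        config.brain_mean_ml + config.brain_sd_ml * rng.standard_normal(n),
        400.0,
    )
    return pd.DataFrame(
        {
            "subject_id": clinical["subject_id"].to_numpy(),
            "wmh_ml": np.exp(log_wmh),
            "brain_ml": brain,
        }
    )


def _ellipsoid(shape, spacing, center_mm, halfaxes_mm) -> np.ndarray:
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    acc = np.zeros(shape, dtype=float)
    for g, c, h in zip(grids, center_mm, halfaxes_mm):
        acc += ((g - c) / h) ** 2
    return acc <= 1.0


def _texture_score(subject: pd.Series | dict, config: CohortConfig) -> float:
    """Scalar in roughly [-1, 1] driving per-subject texture heterogeneity."""
    score = 0.0
    for name, amp in config.texture_coefs.items():
        if name == "age":
            z = (float(subject["age"]) - config.age_mean) / config.age_sd
        else:
            p = config.prevalences.get(name, 0.5)
            v = subject[name]
            z = 0.0 if pd.isna(v) else float(v) - p
        score += amp * z
    return float(np.tanh(score))


def synthesize_phantom(
    subject: pd.Series | dict,
    wmh_ml: float,
    spec: PhantomSpec | None = None,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> tuple[VolumeImage, dict]:
    """Build one phantom intensity volume plus brain/ventricle/WMH masks.

    Brain is a rasterized ellipsoid, ventricles a central ellipsoid pair, and
    the WMH mask the requested number of voxels chosen by a periventricular
    propensity field (distance decay from the ventricles plus smooth seeded
    noise), so the lesion volume matches ``wmh_ml`` to voxel rounding.
    Intensities are tissue baseline plus covariate-modulated noise and
    smooth patches, with bright lesions. Returns ``(image, masks)`` where
    ``masks`` has keys ``brain``, ``ventricles``, ``wmh``.
    """
    spec = spec or PhantomSpec()
    config = config or CohortConfig()
    spec.validate()
    rng = np.random.default_rng(seed)
    shape, spacing = spec.shape, spec.spacing
    center = [n * s / 2 for n, s in zip(shape, spacing)]

    brain = _ellipsoid(shape, spacing, center, spec.brain_halfaxes_mm)
    vent = np.zeros(shape, dtype=bool)
    for sign in (-1.0, 1.0):
        c = list(center)
        c[0] += sign * spec.ventricle_offset_mm
        vent |= _ellipsoid(shape, spacing, c, spec.ventricle_halfaxes_mm)
    vent &= brain

    vox_ml = float(np.prod(spacing)) / 1000.0
    n_wmh = int(round(wmh_ml / vox_ml))
    candidates = brain & ~vent
    if n_wmh > int(candidates.sum()):
        raise ValueError(
            f"requested WMH volume {wmh_ml:.1f} mL exceeds available brain volume"
        )
    wmh = np.zeros(shape, dtype=bool)
    if n_wmh > 0:
        dist = ndimage.distance_transform_edt(~vent, sampling=spacing)
        field = np.exp(-dist / 12.0)
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
        propensity = field + 0.15 * noise
        propensity[~candidates] = -np.inf
        idx = np.argpartition(propensity.ravel(), -n_wmh)[-n_wmh:]
        wmh.ravel()[idx] = True

    score = _texture_score(subject, config)
    noise_sd = spec.noise_sd * (1.0 + 0.5 * score)
    img = np.zeros(shape, dtype=float)
    img[brain] = spec.tissue_intensity
    img[vent] = spec.csf_intensity
    img += noise_sd * rng.standard_normal(shape)
    sigma_vox = [spec.patch_sigma_mm / s for s in spacing]
    patches = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    patches /= max(patches.std(), 1e-12)
    img[brain] += spec.patch_amplitude * (1.0 + score) * patches[brain]
    img[wmh] = spec.wmh_intensity + noise_sd * rng.standard_normal(int(wmh.sum()))
    img[~brain & ~vent] = np.abs(img[~brain & ~vent]) * 0.05

    masks = {
        "brain": VolumeImage(brain, spacing),
        "ventricles": VolumeImage(vent, spacing),
        "wmh": VolumeImage(wmh, spacing),
    }
    return VolumeImage(img, spacing), masks


def generate_feature_table(
    n: int,
    p_features: int,
    rho_true: tuple | float = (0.8,),
    n_informative: int = 10,
    beta_scale: float = 1.0,
    noise_sd: float = 0.5,
    feature_noise: float = 0.7,
    n_clinical: int = 7,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame, GroundTruth]:
    """Feature table with planted burden coefficients and canonical structure.

    Each planted canonical pair ``m`` has latent ``z_x`` and
    ``z_y = rho_m * z_x + sqrt(1 - rho_m^2) * xi``. Feature column ``m`` and
    clinical column ``m`` carry their latent verbatim, so the population
    m-th canonical correlation equals ``rho_m`` exactly; the remaining
    informative features load on the latents with independent noise, the
    rest are pure noise. Burden = X @ beta_true + noise_sd * eps with
    ``n_informative`` nonzero coefficients of size ``beta_scale``.

    Returns ``(features, burden, clinical, ground_truth)``.
    """
    rhos = tuple(np.atleast_1d(rho_true).astype(float))
    if any(not (0.0 <= r < 1.0) for r in rhos):
        raise ValueError(f"rho_true entries must lie in [0, 1), got {rhos}")
    if p_features < max(n_informative, len(rhos)):
        raise ValueError("p_features must cover the informative features")
    if n_clinical < len(rhos):
        raise ValueError("n_clinical must cover the planted canonical pairs")
    rng = np.random.default_rng(seed)
    m = len(rhos)

    zx = rng.standard_normal((n, m))
    zy = np.column_stack(
        [
            r * zx[:, j] + math.sqrt(1 - r**2) * rng.standard_normal(n)
            for j, r in enumerate(rhos)
        ]
    ) if m else np.empty((n, 0))

    X = rng.standard_normal((n, p_features))
    feat_load = np.zeros((p_features, m))
    for j in range(m):
        X[:, j] = zx[:, j]
        feat_load[j, j] = 1.0
    a = math.sqrt(max(1.0 - feature_noise**2, 0.0))
    for i in range(m, n_informative):
        j = i % max(m, 1) if m else 0
        if m:
            X[:, i] = a * zx[:, j] + feature_noise * rng.standard_normal(n)
            feat_load[i, j] = a

    names = [f"feat_{i:04d}" for i in range(p_features)]
    features = pd.DataFrame(X, columns=names)
    features.insert(0, "subject_id", [f"sub-{i + 1:05d}" for i in range(n)])

    beta = np.zeros(p_features)
    beta[:n_informative] = beta_scale
    y = X @ beta + noise_sd * rng.standard_normal(n)

    clin_load = np.zeros((n_clinical, m))
    C = rng.standard_normal((n, n_clinical))
    for j in range(m):
        C[:, j] = zy[:, j]
        clin_load[j, j] = 1.0
    clin_names = ["age", "sex_female", "htn", "dm", "af", "cad", "smoking"][:n_clinical]
    clin_names += [f"clin_{j}" for j in range(len(clin_names), n_clinical)]
    clinical = pd.DataFrame(C, columns=clin_names)
    clinical.insert(0, "subject_id", features["subject_id"].to_numpy())

    gt = GroundTruth(
        feature_names=names,
        beta_true=beta,
        rho_true=rhos,
        informative_features=names[:n_informative],
        clinical_loadings=clin_load,
        feature_loadings=feat_load,
    )
    return features, y, clinical, gt
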