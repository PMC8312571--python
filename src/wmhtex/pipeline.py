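"""End-to-end orchestration: simulate -> mask -> extract -> predict -> CCA.

Each stage reads/writes plain files (NIfTI volumes, CSV tables, YAML
configs, JSON manifests) so stages can be re-run independently; a run
manifest records the config snapshot, per-stage seeds and output checksums
for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cca import PermutationCCA, canonical_summaries, normalize_for_cca
from .masking import MaskSet, cohort_burden, wmh_fraction
from .prediction import RepeatedNestedElasticNet
from .radiomics import ExtractionConfig, extract_features, feature_dictionary
from .synthetic import (
    BINARY_COLUMNS,
    CohortConfig,
    PhantomSpec,
    generate_clinical_cohort,
    generate_wmh_volumes,
    synthesize_phantom,
)
from .volume import load_nifti, save_nifti

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "impute_clinical_medians", "run_pipeline", "stage_seed"]

STAGES = ("simulate", "mask", "extract", "predict", "cca")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed by hashing;
    independent of stage execution order. Kept below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    n_repetitions: int = 30
    n_permutations: int = 1000
    cca_max_features: int | None = None
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        for key, sub in (
            ("cohort", CohortConfig),
            ("phantom", PhantomSpec),
            ("extraction", ExtractionConfig),
        ):
            if key in raw:
                d = dict(raw.pop(key))
                for f_ in dataclasses.fields(sub):
                    if f_.name in d and isinstance(d[f_.name], list):
                        d[f_.name] = tuple(d[f_.name])
                kw[key] = sub(**d)
        for key in ("n_repetitions", "n_permutations", "cca_max_features", "seed"):
            if key in raw:
                kw[key] = raw.pop(key)
        if "stages" in raw:
            kw["stages"] = tuple(raw.pop("stages"))
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "cohort": dataclasses.asdict(self.cohort),
            "phantom": dataclasses.asdict(self.phantom),
            "extraction": dataclasses.asdict(self.extraction),
            "n_repetitions": self.n_repetitions,
            "n_permutations": self.n_permutations,
            "cca_max_features": self.cca_max_features,
            "stages": list(self.stages),
            "seed": self.seed,
        }


def impute_clinical_medians(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Median-impute missing clinical values; drop rows missing age or sex.

    Binary columns use the rounded median (a 0.5 tie resolves to the column
    mode). The report counts dropped rows and imputed cells per column.
    """
    df = table.copy()
    report: dict = {"dropped_missing_age_or_sex": 0, "imputed": {}}
    essential = df["age"].notna() & df["sex_female"].notna()
    report["dropped_missing_age_or_sex"] = int((~essential).sum())
    df = df[essential].reset_index(drop=True)
    for col in df.columns:
        if col in ("subject_id", "site"):
            continue
        miss = df[col].isna()
        if not miss.any():
            continue
        if df[col].notna().sum() == 0:
            raise ValueError(f"column {col!r} entirely missing")
        med = df[col].median()
        if col in BINARY_COLUMNS:
            med = float(df[col].mode().iloc[0]) if med == 0.5 else float(round(med))
        df.loc[miss, col] = med
        report["imputed"][col] = int(miss.sum())
    return df, report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    seed = stage_seed(cfg.seed, "simulate")
    cohort = dataclasses.replace(cfg.cohort, seed=seed)
    clinical = generate_clinical_cohort(cohort)
    clinical.to_csv(out / "clinical.csv", index=False)
    vols = generate_wmh_volumes(clinical, cohort)
    vols.to_csv(out / "volumes_true.csv", index=False)
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    # realistic lesion volumes occasionally exceed what a desk-scale phantom
    # can host; cap at ~30% of the phantom brain ellipsoid
    a, b, c = cfg.phantom.brain_halfaxes_mm
    cap_ml = 0.3 * (4.0 / 3.0) * np.pi * a * b * c / 1000.0
    for i, row in clinical.iterrows():
        sid = row["subject_id"]
        wmh_ml = float(vols.loc[i, "wmh_ml"])
        if wmh_ml > cap_ml:
            logger.warning("clipping %s WMH volume %.1f mL to %.1f mL", sid, wmh_ml, cap_ml)
            wmh_ml = cap_ml
        img, masks = synthesize_phantom(row, wmh_ml, cfg.phantom, cohort, seed=seed + 17 + i)
        save_nifti(img, img_dir / f"{sid}_flair.nii.gz")
        for name, m in masks.items():
            save_nifti(m, img_dir / f"{sid}_{name}.nii.gz")
    truth = {
        "seed": int(seed),
        "burden_coefs": {k: float(v) for k, v in cohort.burden_coefs.items()},
        "texture_coefs": {k: float(v) for k, v in cohort.texture_coefs.items()},
        "wmh_mu_log": float(cohort.wmh_mu_log),
        "wmh_sigma_log": float(cohort.wmh_sigma_log),
    }
    (out / "ground_truth.yaml").write_text(yaml.safe_dump(truth))


def _subject_ids(out: Path) -> list[str]:
    return pd.read_csv(out / "clinical.csv")["subject_id"].tolist()


def _load_masks(img_dir: Path, sid: str) -> MaskSet:
    return MaskSet(
        load_nifti(img_dir / f"{sid}_brain.nii.gz"),
        load_nifti(img_dir / f"{sid}_ventricles.nii.gz"),
        load_nifti(img_dir / f"{sid}_wmh.nii.gz"),
    )


def _stage_mask(cfg: RunConfig, out: Path) -> None:
    img_dir = out / "images"
    rows = []
    for sid in _subject_ids(out):
        masks = _load_masks(img_dir, sid)
        frac, wmh_ml, brain_ml = wmh_fraction(masks)
        rows.append({"subject_id": sid, "wmh_ml": wmh_ml, "brain_ml": brain_ml})
        logger.info("mask subject=%s wmh_ml=%.3f brain_ml=%.1f", sid, wmh_ml, brain_ml)
    burden = cohort_burden(pd.DataFrame(rows))
    burden.to_csv(out / "burden.csv", index=False)


def _stage_extract(cfg: RunConfig, out: Path) -> None:
    img_dir = out / "images"
    rows = []
    for sid in _subject_ids(out):
        image = load_nifti(img_dir / f"{sid}_flair.nii.gz")
        feats = extract_features(image, _load_masks(img_dir, sid), cfg.extraction)
        rows.append({"subject_id": sid, **feats})
        logger.info("extract subject=%s n_features=%d", sid, len(feats))
    table = pd.DataFrame(rows)
    table.to_csv(out / "features.csv", index=False)
    fdict = feature_dictionary([c for c in table.columns if c != "subject_id"])
    (out / "feature_dictionary.json").write_text(json.dumps(fdict, indent=1))


def _stage_predict(cfg: RunConfig, out: Path) -> None:
    feats = pd.read_csv(out / "features.csv")
    burden = pd.read_csv(out / "burden.csv")
    merged = feats.merge(burden[["subject_id", "burden"]], on="subject_id")
    X = merged.drop(columns=["subject_id", "burden"])
    y = merged["burden"].to_numpy()
    model = RepeatedNestedElasticNet(
        n_repetitions=cfg.n_repetitions, random_state=stage_seed(cfg.seed, "predict")
    ).fit(X, y)
    sids = merged["subject_id"].to_numpy()
    preds = model.predictions_frame(sids)
    preds["y_true"] = y[[list(sids).index(s) for s in preds["subject_id"]]]
    preds.to_csv(out / "predictions.csv", index=False)
    pd.DataFrame(
        [
            {"repetition": r.repetition, "r2": r.r2, "n_test": len(r.test_index),
             "n_selected": len(r.selected), "alpha": r.alpha, "l1_ratio": r.l1_ratio}
            for r in model.repetitions_
        ]
    ).to_csv(out / "metrics.csv", index=False)
    model.selection_frequency_.rename_axis("feature").rename("frequency").to_csv(
        out / "selection_frequency.csv"
    )
    pd.DataFrame({"feature": model.signature_}).assign(
        frequency=cfg.n_repetitions
    ).to_csv(out / "signature.csv", index=False)
    (out / "predict_summary.json").write_text(
        json.dumps(
            {
                "r2_mean": model.r2_mean_,
                "r2_std": model.r2_std_,
                "n_oos_predictions": model.n_oos_predictions_,
                "n_signature": len(model.signature_),
                "n_selected_mean": model.n_selected_mean_,
                "n_selected_std": model.n_selected_std_,
            },
            indent=1,
        )
    )


def _full_rank_subset(X: pd.DataFrame) -> pd.DataFrame:
    """Keep a numerically independent column subset (QR with column pivoting);
    small cohorts can make signature features collinear, which CCA rejects."""
    from scipy import linalg

    A = X.to_numpy(dtype=float)
    A = (A - A.mean(axis=0)) / A.std(axis=0)
    _, Rq, piv = linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rq))
    rank = int((diag > 1e-6 * diag.max()).sum())
    if rank < X.shape[1]:
        keep = sorted(piv[:rank])
        logger.warning("dropping %d collinear signature features", X.shape[1] - rank)
        return X.iloc[:, keep]
    return X


def _stage_cca(cfg: RunConfig, out: Path) -> None:
    feats = pd.read_csv(out / "features.csv")
    sig = pd.read_csv(out / "signature.csv")["feature"].tolist()
    clinical, _ = impute_clinical_medians(pd.read_csv(out / "clinical.csv"))
    merged = feats.merge(clinical, on="subject_id")
    clin_cols = ["age"] + list(BINARY_COLUMNS)
    n = len(merged)
    max_p = cfg.cca_max_features or max(n - len(clin_cols) - 2, 1)
    if len(sig) > max_p:
        logger.warning("truncating signature from %d to %d features for CCA", len(sig), max_p)
        sig = sig[:max_p]
    if not sig:
        raise RuntimeError("empty radiomic signature; cannot run CCA")
    X = merged[sig]
    # drop columns that are constant in this cohort (CCA rejects them)
    X = X.loc[:, X.std() > 0]
    Y = merged[clin_cols]
    const = [c for c in Y.columns if Y[c].nunique() < 2]
    if const:
        logger.warning("dropping constant clinical columns from CCA: %s", const)
        Y = Y.drop(columns=const)
    Xn, xlog = normalize_for_cca(X, continuous=list(X.columns))
    Yn, ylog = normalize_for_cca(Y, continuous=["age"])
    Xn = _full_rank_subset(Xn)
    model = PermutationCCA(
        n_permutations=cfg.n_permutations, random_state=stage_seed(cfg.seed, "cca")
    ).fit(Xn, Yn)
    summaries = canonical_summaries(model)
    model.wilks_.to_csv(out / "cca_tests.csv", index=False)
    summaries.x_loadings.rename_axis("feature").to_csv(out / "cca_loadings_radiomic.csv")
    summaries.y_loadings.rename_axis("variable").to_csv(out / "cca_loadings_clinical.csv")
    summaries.explained_variance.to_csv(out / "cca_explained_variance.csv", index=False)
    summaries.biloadings.to_csv(out / "cca_biloadings.csv", index=False)
    pd.concat([xlog, ylog], ignore_index=True).to_csv(out / "cca_transform_log.csv", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "mask": _stage_mask,
    "extract": _stage_extract,
    "predict": _stage_predict,
    "cca": _stage_cca,
}

_STAGE_OUTPUTS = {
    "simulate": ["clinical.csv", "volumes_true.csv", "ground_truth.yaml"],
    "mask": ["burden.csv"],
    "extract": ["features.csv", "feature_dictionary.json"],
    "predict": ["predictions.csv", "metrics.csv", "signature.csv", "predict_summary.json"],
    "cca": ["cca_tests.csv", "cca_loadings_radiomic.csv", "cca_loadings_clinical.csv",
            "cca_explained_variance.csv", "cca_biloadings.csv"],
}


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages in order and write a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    for stage in STAGES:
        if stage not in config.stages:
            manifest["stages"][stage] = {"skipped": True}
            continue
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        outputs = {
            f: _sha256(out / f) for f in _STAGE_OUTPUTS[stage] if (out / f).exists()
        }
        manifest["stages"][stage] = {
            "skipped": False,
            "seed": stage_seed(config.seed, stage),
            "seconds": round(time.time() - t0, 3),
            "outputs": outputs,
        }
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
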