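"""Calibration, determinism and planted-structure checks for the cohort
generator."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wmhtex.synthetic import (
    BINARY_COLUMNS,
    CLINICAL_COLUMNS,
    CohortConfig,
    PhantomSpec,
    generate_clinical_cohort,
    generate_feature_table,
    generate_wmh_volumes,
    synthesize_phantom,
)


class TestClinicalCohort:
    def test_marginals_within_three_standard_errors(self):
        cfg = CohortConfig(n_subjects=4163, seed=7)
        df = generate_clinical_cohort(cfg)
        assert len(df) == 4163
        se_age = cfg.age_sd / math.sqrt(len(df))
        assert abs(df["age"].mean() - 62.8) < 3 * se_age
        for col in BINARY_COLUMNS:
            p = cfg.prevalences[col]
            se = math.sqrt(p * (1 - p) / len(df))
            assert abs(df[col].mean() - p) < 3 * se, col

    def test_empty_cohort_keeps_schema(self):
        df = generate_clinical_cohort(CohortConfig(n_subjects=0))
        assert len(df) == 0
        assert tuple(df.columns) == CLINICAL_COLUMNS

    def test_degenerate_prevalence_one(self):
        cfg = CohortConfig(n_subjects=50, seed=1)
        cfg.prevalences["htn"] = 1.0
        assert (generate_clinical_cohort(cfg)["htn"] == 1).all()

    def test_seed_determinism_and_unique_ids(self):
        a = generate_clinical_cohort(CohortConfig(n_subjects=200, seed=3))
        b = generate_clinical_cohort(CohortConfig(n_subjects=200, seed=3))
        pd.testing.assert_frame_equal(a, b)
        assert a["subject_id"].is_unique

    def test_age_respects_truncation_bounds(self):
        df = generate_clinical_cohort(CohortConfig(n_subjects=2000, seed=5))
        assert df["age"].between(18, 100).all()

    @pytest.mark.parametrize(
        "field,value", [("age_sd", -1.0), ("wmh_sigma_log", -0.1), ("missing_rate", 1.5)]
    )
    def test_invalid_config_rejected_with_parameter_name(self, field, value):
        cfg = CohortConfig(n_subjects=10)
        setattr(cfg, field, value)
        with pytest.raises(ValueError, match=field):
            generate_clinical_cohort(cfg)


class TestWMHVolumes:
    def test_lognormal_median_and_iqr_match_cohort(self):
        cfg = CohortConfig(n_subjects=4163, seed=7)  # no covariate effects
        clin = generate_clinical_cohort(cfg)
        v = generate_wmh_volumes(clin, cfg)["wmh_ml"]
        assert np.median(v) == pytest.approx(4.2, abs=0.3)
        q1, q3 = np.percentile(v, [25, 75])
        assert q1 == pytest.approx(1.4, rel=0.15)
        assert q3 == pytest.approx(11.2, rel=0.15)

    def test_degenerate_sigma_gives_constant_volumes(self):
        cfg = CohortConfig(n_subjects=30, seed=0, wmh_sigma_log=0.0)
        clin = generate_clinical_cohort(cfg)
        v = generate_wmh_volumes(clin, cfg)["wmh_ml"]
        assert np.allclose(v, math.exp(cfg.wmh_mu_log))

    def test_planted_age_effect_has_positive_spearman(self):
        cfg = CohortConfig(n_subjects=2000, seed=2, burden_coefs={"age": 0.5})
        clin = generate_clinical_cohort(cfg)
        v = generate_wmh_volumes(clin, cfg)
        rho = stats.spearmanr(clin["age"], v["wmh_ml"]).statistic
        assert rho > 0.1

    def test_empty_clinical_rejected(self):
        cfg = CohortConfig(n_subjects=0)
        with pytest.raises(ValueError):
            generate_wmh_volumes(generate_clinical_cohort(cfg), cfg)


class TestPhantom:
    def _subject(self):
        return generate_clinical_cohort(CohortConfig(n_subjects=1, seed=9)).iloc[0]

    def test_zero_burden_gives_empty_wmh_but_brain_present(self):
        img, masks = synthesize_phantom(self._subject(), 0.0, seed=1)
        assert not masks["wmh"].data.any()
        assert masks["brain"].data.any() and masks["ventricles"].data.any()

    def test_same_seed_voxel_identical(self):
        a_img, a_m = synthesize_phantom(self._subject(), 5.0, seed=4)
        b_img, b_m = synthesize_phantom(self._subject(), 5.0, seed=4)
        assert np.array_equal(a_img.data, b_img.data)
        for k in a_m:
            assert np.array_equal(a_m[k].data, b_m[k].data)

    def test_requested_volume_recovered_from_voxel_count(self):
        _, masks = synthesize_phantom(self._subject(), 5.0, seed=3)
        assert masks["wmh"].volume_ml() == pytest.approx(5.0, rel=0.05)

    def test_mask_geometry_nesting(self):
        _, m = synthesize_phantom(self._subject(), 8.0, seed=5)
        brain, vent, wmh = m["brain"].as_bool(), m["ventricles"].as_bool(), m["wmh"].as_bool()
        assert not (wmh & vent).any()
        assert (wmh <= brain).all() and (vent <= brain).all()

    def test_excessive_burden_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            synthesize_phantom(self._subject(), 1e5, seed=0)


class TestFeatureTable:
    def test_null_association_near_chance(self):
        X, y, clin, gt = generate_feature_table(
            5000, 10, rho_true=(0.0,), n_clinical=3, seed=0
        )
        from wmhtex.cca import PermutationCCA

        m = PermutationCCA(n_permutations=0).fit(
            X.drop(columns="subject_id"), clin.drop(columns="subject_id")
        )
        assert m.correlations_[0] < 0.1

    def test_noiseless_burden_is_exact_linear_combination(self):
        X, y, clin, gt = generate_feature_table(200, 20, noise_sd=0.0, seed=1)
        Xv = X.drop(columns="subject_id").to_numpy()
        assert np.allclose(y, Xv @ gt.beta_true)

    def test_planted_canonical_correlation_recovered(self):
        X, y, clin, gt = generate_feature_table(5000, 10, rho_true=(0.8,), seed=2)
        from wmhtex.cca import PermutationCCA

        m = PermutationCCA(n_permutations=0).fit(
            X.drop(columns="subject_id"), clin.drop(columns="subject_id")
        )
        assert abs(m.correlations_[0] - 0.8) < 0.05

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho_true"):
            generate_feature_table(100, 10, rho_true=(1.0,))
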