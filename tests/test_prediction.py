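"""Nested CV machinery: stratified folds, leakage, hyperparameter limits,
signature stability, site transfer and residual diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.dummy import DummyRegressor

from wmhtex.prediction import (
    RepeatedNestedElasticNet,
    RepetitionResult,
    fit_elastic_net,
    leave_one_site_out_cv,
    repeated_nested_cv,
    residuals_by_group,
    stable_signature,
    standardize_features,
    stratified_outcome_folds,
)
from wmhtex.synthetic import generate_feature_table


class TestStandardize:
    def test_full_fit_gives_unit_columns(self, rng):
        df = pd.DataFrame(rng.random((50, 4)) * 9, columns=list("abcd"))
        out, mu, sd = standardize_features(df)
        assert np.allclose(out.mean(), 0, atol=1e-12)
        assert np.allclose(out.std(ddof=0), 1)

    def test_constant_column_dropped(self, rng):
        df = pd.DataFrame({"a": rng.random(20), "b": np.ones(20)})
        out, _, _ = standardize_features(df)
        assert list(out.columns) == ["a"]

    def test_no_leakage_from_held_out_rows(self, rng):
        df = pd.DataFrame(rng.standard_normal((100, 3)) + 5, columns=list("xyz"))
        train = np.arange(60)
        out, mu, sd = standardize_features(df, train)
        assert np.allclose(out.iloc[train].mean(), 0, atol=1e-12)
        # test rows standardized with train statistics: mean generally != 0
        assert not np.allclose(out.iloc[60:].mean(), 0, atol=1e-3)


class TestStratifiedFolds:
    def test_fold_sizes_for_study_cohort(self, rng):
        y = rng.standard_normal(4163)
        folds = stratified_outcome_folds(y, 5, seed=0)
        assert sorted(np.bincount(folds), reverse=True) == [833, 833, 833, 832, 832]

    def test_leave_one_out_degenerate(self, rng):
        y = rng.standard_normal(12)
        folds = stratified_outcome_folds(y, 12, seed=0)
        assert (np.bincount(folds) == 1).all()

    def test_fold_means_close_to_grand_mean(self, rng):
        y = np.sort(rng.standard_normal(1000))
        folds = stratified_outcome_folds(y, 5, bins=10, seed=1)
        for f in range(5):
            assert abs(y[folds == f].mean() - y.mean()) < 0.2 * y.std()


class TestNestedCV:
    def test_out_of_sample_prediction_bookkeeping(self):
        X, y, _, _ = generate_feature_table(4163, 3, rho_true=(0.0,), n_informative=1, seed=0)
        m = RepeatedNestedElasticNet(n_repetitions=30, estimator=DummyRegressor()).fit(
            X.drop(columns="subject_id"), y
        )
        assert m.n_oos_predictions_ == 24990
        assert all(len(r.test_index) == 833 for r in m.repetitions_)

    def test_noiseless_planted_model_predicted_almost_perfectly(self):
        X, y, _, _ = generate_feature_table(300, 20, noise_sd=0.0, seed=3)
        m = RepeatedNestedElasticNet(n_repetitions=2, random_state=0).fit(
            X.drop(columns="subject_id"), y
        )
        assert m.r2_mean_ > 0.99

    def test_vanishing_penalty_matches_least_squares(self, rng):
        n, p = 500, 5
        X = rng.standard_normal((n, p))
        beta = rng.standard_normal(p)
        y = X @ beta + 0.1 * rng.standard_normal(n)
        model = fit_elastic_net(X, y, alpha=1e-10, l1_ratio=0.5, tol=1e-12)
        ols = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
        assert np.allclose(model.coef_, ols[1:], atol=1e-4)

    def test_predictions_only_for_held_out_subjects(self):
        X, y, _, _ = generate_feature_table(200, 5, n_informative=3, seed=4)
        m = RepeatedNestedElasticNet(n_repetitions=3, random_state=1).fit(
            X.drop(columns="subject_id"), y
        )
        for rep in m.repetitions_:
            assert len(set(rep.test_index)) == len(rep.test_index)
            assert len(rep.test_index) == int(np.ceil(200 / 5))

    def test_non_finite_outcome_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).random((20, 3)))
        y = np.full(20, np.nan)
        with pytest.raises(ValueError, match="finite"):
            RepeatedNestedElasticNet(n_repetitions=1).fit(X, y)

    def test_empty_feature_subset_rejected(self):
        X, y, _, _ = generate_feature_table(50, 4, n_informative=2, seed=0)
        with pytest.raises(ValueError, match="empty"):
            repeated_nested_cv(X.drop(columns="subject_id"), y, feature_subset=[])


class TestSignature:
    def test_intersection_of_selected_sets(self):
        reps = [
            RepetitionResult(0, np.array([0]), np.array([0.0]), 0.0, ["A", "B", "C"], 1, 1),
            RepetitionResult(1, np.array([0]), np.array([0.0]), 0.0, ["A", "B"], 1, 1),
            RepetitionResult(2, np.array([0]), np.array([0.0]), 0.0, ["A", "D"], 1, 1),
        ]
        sig, freq = stable_signature(reps)
        assert sig == ["A"]
        assert freq["A"] == 3 and freq["D"] == 1

    def test_single_repetition_signature_is_its_set(self):
        reps = [RepetitionResult(0, np.array([0]), np.array([0.0]), 0.0, ["B", "A"], 1, 1)]
        sig, _ = stable_signature(reps)
        assert sig == ["A", "B"]

    def test_signature_subset_of_every_repetition(self):
        X, y, _, gt = generate_feature_table(300, 40, noise_sd=0.5, seed=6)
        m = RepeatedNestedElasticNet(n_repetitions=4, random_state=2).fit(
            X.drop(columns="subject_id"), y
        )
        for rep in m.repetitions_:
            assert set(m.signature_) <= set(rep.selected)
        assert (m.selection_frequency_[m.signature_] == 4).all()


class TestSiteTransfer:
    def test_two_exchangeable_sites_have_similar_r2(self):
        X, y, _, _ = generate_feature_table(400, 10, noise_sd=0.5, seed=7)
        sites = np.array(["a", "b"] * 200)
        table = leave_one_site_out_cv(X.drop(columns="subject_id"), y, sites)
        assert len(table) == 2
        assert abs(table["r2"].iloc[0] - table["r2"].iloc[1]) < 0.1
        assert (table["r2"] > 0.8).all()

    def test_shifted_site_predicts_worse(self, rng):
        X, y, _, gt = generate_feature_table(400, 10, noise_sd=0.5, seed=8)
        Xv = X.drop(columns="subject_id").copy()
        sites = np.array(["match"] * 300 + ["shifted"] * 100)
        # distort the held-out site's feature scale (covariate shift)
        Xv.iloc[300:] = Xv.iloc[300:] * 3.0 + 2.0
        table = leave_one_site_out_cv(Xv, y, sites).set_index("site")
        assert table.loc["shifted", "r2"] < table.loc["match", "r2"]

    def test_single_site_rejected(self):
        X, y, _, _ = generate_feature_table(50, 4, n_informative=2, seed=0)
        with pytest.raises(ValueError, match="two sites"):
            leave_one_site_out_cv(X.drop(columns="subject_id"), y, np.zeros(50))


class TestResiduals:
    def _fitted(self, n=200, seed=9):
        X, y, _, _ = generate_feature_table(n, 5, n_informative=3, noise_sd=0.3, seed=seed)
        m = RepeatedNestedElasticNet(n_repetitions=3, random_state=3).fit(
            X.drop(columns="subject_id"), y
        )
        return m, y

    def test_residual_means_near_zero_without_group_effect(self, rng):
        m, y = self._fitted()
        groups = rng.integers(0, 5, size=200).astype(float)
        table, trend = residuals_by_group(y, m, groups)
        assert trend["p_value"] > 0.001  # no planted trend
        assert abs(table["mean"]).max() < 0.5

    def test_planted_group_offset_detected(self, rng):
        m, y = self._fitted()
        groups = rng.integers(0, 3, size=200).astype(float)
        y2 = y + (groups == 2) * 1.0  # offset group AFTER fitting on y
        table, _ = residuals_by_group(y2, m, groups)
        t = table.set_index("group")
        assert t.loc[2.0, "mean"] > t.loc[0.0, "mean"] + 0.5

    def test_missing_group_labels_reported(self):
        m, y = self._fitted()
        groups = np.full(200, np.nan)
        groups[:150] = 1.0
        _, trend = residuals_by_group(y, m, groups)
        assert trend["n_missing_group"] > 0
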