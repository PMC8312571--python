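"""CCA fit, Wilks/Rao parametric tests, permutation inference, BH and
loading summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wmhtex.cca import (
    PermutationCCA,
    bh_adjust,
    canonical_summaries,
    normalize_for_cca,
    rank_inverse_normal,
    wilks_rao_test,
)
from wmhtex.synthetic import generate_feature_table


class TestNormalizeForCCA:
    def test_normal_sample_left_untouched(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(500)})
        out, log = normalize_for_cca(df, seed=0)
        assert not log["transformed"].iloc[0]
        assert np.allclose(out["x"], df["x"])

    def test_lognormal_sample_transformed_to_normality(self, rng):
        df = pd.DataFrame({"x": np.exp(rng.standard_normal(800))})
        out, log = normalize_for_cca(df, seed=0)
        assert log["transformed"].iloc[0]
        assert stats.shapiro(out["x"]).pvalue > 0.05

    def test_binary_column_exempt(self, rng):
        df = pd.DataFrame({"b": (rng.random(300) < 0.3).astype(float)})
        out, log = normalize_for_cca(df)
        assert log["binary"].iloc[0]
        assert set(np.unique(out["b"])) == {0.0, 1.0}

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_for_cca(pd.DataFrame({"c": np.ones(50)}))

    def test_rank_inverse_normal_is_marginally_normal(self, rng):
        z = rank_inverse_normal(np.exp(rng.standard_normal(400)))
        assert stats.shapiro(z).pvalue > 0.01


class TestCCAFit:
    def test_self_correlation_is_perfect(self, rng):
        X = rng.standard_normal((100, 3))
        m = PermutationCCA(n_permutations=0).fit(X, X.copy())
        assert np.allclose(m.correlations_, 1.0, atol=1e-8)

    def test_independent_sets_near_zero(self, rng):
        m = PermutationCCA(n_permutations=0).fit(
            rng.standard_normal((5000, 10)), rng.standard_normal((5000, 3))
        )
        assert m.correlations_[0] < 0.1

    def test_number_of_functions_is_min_pq(self, rng):
        m = PermutationCCA(n_permutations=0).fit(
            rng.standard_normal((300, 9)), rng.standard_normal((300, 4))
        )
        assert len(m.correlations_) == 4
        assert (np.diff(m.correlations_) <= 1e-12).all()  # sorted descending

    def test_affine_rescaling_invariance(self, rng):
        X = rng.standard_normal((200, 5))
        Y = rng.standard_normal((200, 3))
        a = PermutationCCA(n_permutations=0).fit(X, Y)
        b = PermutationCCA(n_permutations=0).fit(X * [1, 10, 0.1, 5, 2] + 3, Y * 7 - 1)
        assert np.allclose(a.correlations_, b.correlations_, atol=1e-10)

    def test_underdetermined_problem_rejected(self, rng):
        with pytest.raises(ValueError, match="n > p \\+ q"):
            PermutationCCA().fit(rng.standard_normal((10, 8)), rng.standard_normal((10, 5)))

    def test_rank_deficiency_reported(self, rng):
        X = rng.standard_normal((100, 4))
        X[:, 3] = X[:, 0] + X[:, 1]  # exact collinearity
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            PermutationCCA(n_permutations=0).fit(X, rng.standard_normal((100, 2)))


class TestWilksRao:
    def test_reduces_to_pearson_f_test_for_p_q_one(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = 0.4 * x + rng.standard_normal(n)
        r = abs(np.corrcoef(x, y)[0, 1])
        tab = wilks_rao_test(np.array([r]), n, 1, 1)
        f_expected = (n - 2) * r**2 / (1 - r**2)
        assert tab["rao_f"].iloc[0] == pytest.approx(f_expected, abs=1e-8)
        p_expected = stats.f.sf(f_expected, 1, n - 2)
        assert tab["p_parametric"].iloc[0] == pytest.approx(p_expected, abs=1e-10)

    def test_null_correlations_give_lambda_one(self):
        tab = wilks_rao_test(np.zeros(3), 100, 5, 3)
        assert np.allclose(tab["wilks_lambda"], 1.0)
        assert np.allclose(tab["rao_f"], 0.0)
        assert np.allclose(tab["p_parametric"], 1.0)

    def test_lambda_product_of_printed_correlations(self):
        r = np.array([0.81, 0.65, 0.42, 0.24, 0.20, 0.15, 0.15])
        tab = wilks_rao_test(r, 4163, 68, 7)
        assert tab["wilks_lambda"].iloc[0] == pytest.approx(np.prod(1 - r**2), rel=1e-12)
        assert tab["wilks_lambda"].iloc[0] == pytest.approx(0.141, abs=0.005)

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError):
            wilks_rao_test(np.array([1.2]), 100, 2, 2)


class TestPermutation:
    def test_perfect_association_attains_minimum_p(self, rng):
        X = rng.standard_normal((60, 2))
        m = PermutationCCA(n_permutations=99, random_state=0).fit(X, X.copy())
        assert m.p_permutation_[0] == pytest.approx(1 / 100)

    def test_same_seed_reproducible(self, rng):
        X = rng.standard_normal((80, 4))
        Y = rng.standard_normal((80, 3))
        a = PermutationCCA(n_permutations=50, random_state=5).fit(X, Y)
        b = PermutationCCA(n_permutations=50, random_state=5).fit(X, Y)
        assert np.array_equal(a.p_permutation_, b.p_permutation_)

    def test_parametric_and_permutation_agree_in_rank(self):
        # across null multivariate-normal replicates the two p-values co-rank
        # (weak-signal regime so neither test saturates at its minimum)
        p_par, p_perm = [], []
        for rep in range(50):
            g = np.random.default_rng(rep)
            z = g.standard_normal(150)
            rho = 0.25 * rep / 49
            X = np.column_stack([z, g.standard_normal((150, 3))])
            Y = np.column_stack(
                [rho * z + np.sqrt(1 - rho**2) * g.standard_normal(150),
                 g.standard_normal((150, 2))]
            )
            m = PermutationCCA(n_permutations=499, random_state=rep).fit(X, Y)
            p_par.append(m.p_parametric_[0])
            p_perm.append(m.p_permutation_[0])
        rho_s = stats.spearmanr(p_par, p_perm).statistic
        assert rho_s > 0.9

    def test_naive_mode_available(self, rng):
        X = rng.standard_normal((100, 4))
        Y = rng.standard_normal((100, 3))
        m = PermutationCCA(n_permutations=50, random_state=1, higher_order="naive").fit(X, Y)
        assert len(m.p_permutation_) == 3

    def test_zero_permutations_fall_back_to_parametric_fdr(self, rng):
        m = PermutationCCA(n_permutations=0).fit(
            rng.standard_normal((100, 4)), rng.standard_normal((100, 3))
        )
        assert np.isnan(m.p_permutation_).all()
        assert np.all(m.p_fdr_ >= 0)


class TestBH:
    def test_step_up_worked_example(self):
        # sorted: 0.01*3=0.03, 0.03*3/2=0.045, 0.04*3/3=0.04; step-up
        # enforcement caps the middle at 0.04
        adj = bh_adjust(np.array([0.01, 0.04, 0.03]))
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_ties_all_equal(self):
        adj = bh_adjust(np.full(7, 0.2))
        assert np.allclose(adj, 0.2)

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.random(20)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestSummaries:
    def test_univariate_loading_is_unit(self, rng):
        x = rng.standard_normal((100, 1))
        y = 0.5 * x + 0.1 * rng.standard_normal((100, 1))
        m = PermutationCCA(n_permutations=0).fit(x, y)
        s = canonical_summaries(m)
        assert abs(s.x_loadings.iloc[0, 0]) == pytest.approx(1.0)

    def test_loadings_bounded_and_explained_variance_sums_to_one(self, rng):
        X = rng.standard_normal((300, 6))
        Y = rng.standard_normal((300, 4))
        m = PermutationCCA(n_permutations=0).fit(X, Y)
        s = canonical_summaries(m)
        assert (s.x_loadings.abs() <= 1 + 1e-12).all().all()
        assert s.explained_variance["explained_variance"].sum() == pytest.approx(1.0)

    def test_age_driven_factor_dominates_clinical_loadings(self):
        X, _, clin, _ = generate_feature_table(3000, 10, rho_true=(0.8,), seed=5)
        m = PermutationCCA(n_permutations=0).fit(
            X.drop(columns="subject_id"), clin.drop(columns="subject_id")
        )
        s = canonical_summaries(m)
        cf1 = s.y_loadings["CF1"].abs()
        assert cf1.idxmax() == "age"  # the planted latent enters through age
        assert cf1.max() > 0.9

    def test_biloading_coordinates_cover_both_sets(self, rng):
        X = rng.standard_normal((200, 5))
        Y = rng.standard_normal((200, 3))
        m = PermutationCCA(n_permutations=0).fit(X, Y)
        bil = canonical_summaries(m).biloadings
        assert set(bil["set"]) == {"radiomic", "clinical"}
        assert len(bil) == 8
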