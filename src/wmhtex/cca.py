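"""Canonical correlation analysis of the radiomic signature against clinical
phenotypes, with Wilks' Lambda / Rao F parametric tests, permutation tests
and Benjamini-Hochberg correction.

CCA finds paired linear combinations (canonical variates) of two variable
sets maximizing their mutual correlation. It is solved here by singular
value decomposition of the whitened cross-covariance
``Sxx^{-1/2} Sxy Syy^{-1/2}``; the singular values are the canonical
correlations r_1 >= ... >= r_s, s = min(p, q). Function k is tested through
the residual association Lambda_k = prod_{i>=k} (1 - r_i^2) with Rao's F
approximation, and nonparametrically by re-fitting the CCA on row-permuted
Y (the permutation statistic is Lambda_k; smaller means stronger
association).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_for_cca",
    "rank_inverse_normal",
    "PermutationCCA",
    "cca_fit",
    "wilks_rao_test",
    "permutation_pvalues",
    "bh_adjust",
    "canonical_summaries",
]


def rank_inverse_normal(x: np.ndarray) -> np.ndarray:
    """Ordered-quantile (rank-based inverse normal) transform: Phi^-1((r-1/2)/n)."""
    x = np.asarray(x, dtype=float)
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 0.5) / len(x))


def normalize_for_cca(
    table: pd.DataFrame,
    continuous: list | None = None,
    alpha: float = 0.05,
    max_shapiro_n: int = 5000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shapiro-Wilk each continuous column; transform to normality if rejected.

    Binary columns (<= 2 distinct values) are exempt and passed through as
    0/1. Columns rejected at ``alpha`` get the ordered-quantile (rank-based
    inverse normal) transform. Shapiro-Wilk runs on a seeded subsample of at
    most ``max_shapiro_n`` values. Returns (transformed table, per-column
    decision log).
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    log = []
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        nun = len(np.unique(x))
        if nun < 2:
            raise ValueError(f"constant column {col!r}")
        is_binary = nun <= 2
        if continuous is not None:
            treat = col in continuous
        else:
            treat = not is_binary
        if not treat:
            log.append({"column": col, "binary": True, "p_shapiro": np.nan, "transformed": False})
            continue
        sample = x if len(x) <= max_shapiro_n else rng.choice(x, max_shapiro_n, replace=False)
        p = float(stats.shapiro(sample).pvalue)
        rej = p < alpha
        if rej:
            out[col] = rank_inverse_normal(x)
        log.append({"column": col, "binary": False, "p_shapiro": p, "transformed": rej})
    return out, pd.DataFrame(log)


def _whitener(S: np.ndarray, name: str) -> np.ndarray:
    """Inverse symmetric square root of a covariance block, with rank check."""
    vals, vecs = linalg.eigh(S)
    tol = 1e-10 * max(vals.max(), 0.0)
    if vals.min() <= tol:
        rank = int((vals > tol).sum())
        raise np.linalg.LinAlgError(
            f"{name} covariance block rank-deficient (rank {rank} of {S.shape[0]})"
        )
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def wilks_rao_test(
    r: np.ndarray, n: int, p: int, q: int
) -> pd.DataFrame:
    """Per-function Wilks Lambda with Rao's F approximation.

    For function k (1-based) with p' = p - k + 1, q' = q - k + 1:
    Lambda_k = prod_{i>=k} (1 - r_i^2);
    t = sqrt((p'^2 q'^2 - 4) / (p'^2 + q'^2 - 5)) (1 when the denominator
    is <= 0); w = n - (p' + q' + 3)/2; df1 = p' q'; df2 = w t - p' q'/2 + 1;
    F = ((1 - Lambda^(1/t)) / Lambda^(1/t)) * df2/df1.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("canonical correlations must lie in [0, 1]")
    s = len(r)
    rows = []
    for k in range(1, s + 1):
        pp, qq = p - k + 1, q - k + 1
        lam = float(np.prod(1.0 - r[k - 1 :] ** 2))
        den = pp**2 + qq**2 - 5
        t = np.sqrt((pp**2 * qq**2 - 4) / den) if den > 0 else 1.0
        w = n - (pp + qq + 3) / 2.0
        df1 = pp * qq
        df2 = w * t - pp * qq / 2.0 + 1.0
        lam_t = lam ** (1.0 / t)
        F = ((1.0 - lam_t) / lam_t) * (df2 / df1) if lam_t > 0 else np.inf
        pval = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        rows.append(
            {"function": k, "r": float(r[k - 1]), "wilks_lambda": lam, "rao_f": float(F),
             "df1": float(df1), "df2": float(df2), "p_parametric": pval}
        )
    return pd.DataFrame(rows)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


class PermutationCCA(BaseEstimator):
    """Classical CCA with parametric and permutation inference.

    Parameters
    ----------
    n_permutations : label permutations for the nonparametric test (1000).
    random_state : permutation seed.
    scale : standardize columns before fitting (correlations are invariant;
        weights are reported on the standardized scale when True).

    Fitted attributes (s = min(p, q) functions): ``correlations_``,
    ``x_weights_``/``y_weights_``, ``x_scores_``/``y_scores_`` (unit
    variance), ``x_loadings_``/``y_loadings_`` (variable <-> own-variate
    correlations), ``wilks_`` (per-function test table with parametric,
    permutation and BH-adjusted p-values), ``explained_variance_ratio_``
    (r_k^2 / sum r_j^2) and ``variance_extracted_`` (mean squared loading
    per function, the alternative scree convention).
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        random_state: int = 0,
        scale: bool = True,
        higher_order: str = "residualized",
    ):
        self.n_permutations = n_permutations
        self.random_state = random_state
        self.scale = scale
        self.higher_order = higher_order

    def _prep(self, A, name):
        if isinstance(A, pd.DataFrame):
            names = list(A.columns)
            A = A.to_numpy(dtype=float)
        else:
            A = np.asarray(A, dtype=float)
            names = [f"{name}{i}" for i in range(A.shape[1])]
        if not np.all(np.isfinite(A)):
            raise ValueError(f"non-finite values in {name}")
        return A, names

    def fit(self, X, Y):
        X, xnames = self._prep(X, "x")
        Y, ynames = self._prep(Y, "y")
        n, p = X.shape
        q = Y.shape[1]
        if len(Y) != n:
            raise ValueError("X and Y row counts differ")
        if n <= p + q:
            raise ValueError(f"need n > p + q (n={n}, p={p}, q={q})")
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        if self.scale:
            sx, sy = Xc.std(axis=0), Yc.std(axis=0)
            if np.any(sx == 0) or np.any(sy == 0):
                raise ValueError("constant column in X or Y")
            Xc, Yc = Xc / sx, Yc / sy
        Sxx = Xc.T @ Xc / (n - 1)
        Syy = Yc.T @ Yc / (n - 1)
        Wx = _whitener(Sxx, "X")
        Wy = _whitener(Syy, "Y")
        # whitened data: columns are uncorrelated, unit variance
        Xw = Xc @ Wx
        Yw = Yc @ Wy
        K = Xw.T @ Yw / (n - 1)
        U, r, Vt = np.linalg.svd(K, full_matrices=False)
        s = min(p, q)
        r = np.clip(r[:s], 0.0, 1.0)
        A = Wx @ U[:, :s]  # x weights (for standardized columns if scale)
        B = Wy @ Vt.T[:, :s]
        xs = Xc @ A
        ys = Yc @ B
        # unit-variance variates
        xs /= xs.std(axis=0, ddof=1)
        ys /= ys.std(axis=0, ddof=1)

        self.n_samples_, self.n_x_, self.n_y_ = n, p, q
        self.x_names_, self.y_names_ = xnames, ynames
        self.correlations_ = r
        self.x_weights_, self.y_weights_ = A, B
        self.x_scores_, self.y_scores_ = xs, ys
        self.x_loadings_ = _corr_columns(Xc, xs)
        self.y_loadings_ = _corr_columns(Yc, ys)

        table = wilks_rao_test(r, n, p, q)
        if self.n_permutations and self.n_permutations > 0:
            table["p_permutation"] = self._permute(Xc, Yc, Xw, Yw, r)
            table["p_fdr"] = bh_adjust(table["p_permutation"].to_numpy())
        else:
            table["p_permutation"] = np.nan
            table["p_fdr"] = bh_adjust(table["p_parametric"].to_numpy())
        tot = (r**2).sum()
        table["explained_variance"] = r**2 / tot if tot > 0 else 0.0
        self.wilks_ = table
        self.explained_variance_ratio_ = table["explained_variance"].to_numpy()
        self.variance_extracted_x_ = (self.x_loadings_**2).mean(axis=0)
        self.variance_extracted_y_ = (self.y_loadings_**2).mean(axis=0)
        self.p_parametric_ = table["p_parametric"].to_numpy()
        self.p_permutation_ = table["p_permutation"].to_numpy()
        self.p_fdr_ = table["p_fdr"].to_numpy()
        return self

    @staticmethod
    def _whiten_data(A: np.ndarray) -> np.ndarray:
        """Orthonormalize columns (rank-truncated), scaled to unit variance."""
        n = len(A)
        U, svals, _ = np.linalg.svd(A, full_matrices=False)
        tol = max(A.shape) * np.finfo(float).eps * (svals.max() if svals.size else 0.0)
        k = int((svals > tol).sum())
        return U[:, :k] * np.sqrt(n - 1)

    def _permute(self, Xc, Yc, Xw, Yw, r_obs: np.ndarray) -> np.ndarray:
        """Permutation p per function; statistic Lambda_k (small = strong).

        Function 1 permutes rows of whitened Y against whitened X (only the
        cross-covariance block changes under a row permutation). For k >= 2
        the default ``higher_order='residualized'`` scheme first projects the
        leading k-1 canonical variates out of both sets (sequential removal),
        so the test of the k-th function is calibrated even when stronger
        functions carry real association; ``'naive'`` compares Lambda_k of
        the full re-fitted CCA against unresidualized permutations instead.
        """
        if self.higher_order not in ("residualized", "naive"):
            raise ValueError(f"unknown higher_order {self.higher_order!r}")
        n = len(Xw)
        s = len(r_obs)
        n_perm = self.n_permutations
        rng = np.random.default_rng(self.random_state)
        pvals = np.empty(s)
        if self.higher_order == "naive":
            lam_obs = np.array([np.prod(1.0 - r_obs[k:] ** 2) for k in range(s)])
            count = np.zeros(s)
            for _ in range(n_perm):
                perm = rng.permutation(n)
                rp = np.clip(
                    np.linalg.svd(Xw.T @ Yw[perm] / (n - 1), compute_uv=False)[:s], 0, 1
                )
                lam_p = np.array([np.prod(1.0 - rp[k:] ** 2) for k in range(s)])
                count += lam_p <= lam_obs
            return (1.0 + count) / (1.0 + n_perm)
        for k in range(s):
            if k == 0:
                Xr, Yr = Xw, Yw
            else:
                qx, _ = np.linalg.qr(self.x_scores_[:, :k])
                qy, _ = np.linalg.qr(self.y_scores_[:, :k])
                Xr = self._whiten_data(Xc - qx @ (qx.T @ Xc))
                Yr = self._whiten_data(Yc - qy @ (qy.T @ Yc))
            rr = np.clip(np.linalg.svd(Xr.T @ Yr / (n - 1), compute_uv=False), 0, 1)
            lam_obs = float(np.prod(1.0 - rr**2))
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                rp = np.clip(
                    np.linalg.svd(Xr.T @ Yr[perm] / (n - 1), compute_uv=False), 0, 1
                )
                count += float(np.prod(1.0 - rp**2)) <= lam_obs
            pvals[k] = (1.0 + count) / (1.0 + n_perm)
        return pvals

    def transform(self, X, Y):
        check_is_fitted(self, "x_weights_")
        X, _ = self._prep(X, "x")
        Y, _ = self._prep(Y, "y")
        return X @ self.x_weights_, Y @ self.y_weights_


def _corr_columns(A: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of A with each score column."""
    Ac = A - A.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    denom = np.outer(
        np.sqrt((Ac**2).sum(axis=0)), np.sqrt((Sc**2).sum(axis=0))
    )
    return (Ac.T @ Sc) / denom


def cca_fit(X, Y, n_permutations: int = 1000, random_state: int = 0) -> PermutationCCA:
    """Functional wrapper around :class:`PermutationCCA`."""
    return PermutationCCA(n_permutations=n_permutations, random_state=random_state).fit(X, Y)


def permutation_pvalues(X, Y, n_perm: int = 1000, seed: int = 0) -> np.ndarray:
    """Permutation p-values only (refits the CCA under row-permuted Y)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    return PermutationCCA(n_permutations=n_perm, random_state=seed).fit(X, Y).p_permutation_


@dataclass
class CanonicalSummaries:
    x_loadings: pd.DataFrame
    y_loadings: pd.DataFrame
    explained_variance: pd.DataFrame
    biloadings: pd.DataFrame


def canonical_summaries(model: PermutationCCA) -> CanonicalSummaries:
    """Loadings tables, scree fractions (both conventions) and bi-loading
    coordinates (each variable's loadings on functions 1 and 2)."""
    check_is_fitted(model, "x_loadings_")
    s = len(model.correlations_)
    fcols = [f"CF{k + 1}" for k in range(s)]
    xl = pd.DataFrame(model.x_loadings_, index=model.x_names_, columns=fcols)
    yl = pd.DataFrame(model.y_loadings_, index=model.y_names_, columns=fcols)
    ev = pd.DataFrame(
        {
            "function": np.arange(1, s + 1),
            "r": model.correlations_,
            "explained_variance": model.explained_variance_ratio_,
            "variance_extracted_x": model.variance_extracted_x_,
            "variance_extracted_y": model.variance_extracted_y_,
        }
    )
    k2 = min(s, 2)
    bil = pd.concat(
        [
            pd.DataFrame(
                {
                    "variable": model.x_names_,
                    "set": "radiomic",
                    "cf1": model.x_loadings_[:, 0],
                    "cf2": model.x_loadings_[:, k2 - 1] if k2 > 1 else 0.0,
                }
            ),
            pd.DataFrame(
                {
                    "variable": model.y_names_,
                    "set": "clinical",
                    "cf1": model.y_loadings_[:, 0],
                    "cf2": model.y_loadings_[:, k2 - 1] if k2 > 1 else 0.0,
                }
            ),
        ],
        ignore_index=True,
    )
    return CanonicalSummaries(xl, yl, ev, bil)
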