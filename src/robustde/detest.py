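"""Per-gene robust two-sample t-test with fold-change regulation calls.

The workflow mirrors the standard two-group expression screen: per-gene
z-score normalization, a Welch-style two-sample t-statistic in which the
group means and variances are the minimum beta-divergence estimates (see
:mod:`robustde.beta`), two-sided p-values from the t distribution with
Satterthwaite degrees of freedom, and an up/down regulation call combining
the p-value with a log2 fold-change threshold computed on the original
count scale.

Effective sample sizes: downweighted observations should not count as full
observations, so the standard errors use ``n_g~ = sum of final beta-weights``
in group g, which reduces to the true n when beta = 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .beta import _SIGMA2_FLOOR, _fit_matrix

__all__ = [
    "zscore_transform",
    "log2_fold_change",
    "robust_t_statistic",
    "robust_t_test",
    "classical_t_test",
    "RobustTTest",
]

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "not_significant"


def _as_matrix(matrix):
    """Return (values, gene_ids, columns) from a DataFrame or ndarray."""
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), matrix.index.astype(str), matrix.columns
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D genes x samples matrix")
    ids = pd.Index([f"g{i}" for i in range(arr.shape[0])])
    return arr, ids, pd.RangeIndex(arr.shape[1])


def zscore_transform(matrix):
    """Row-wise z-score normalization across all samples jointly.

    Each gene row is mapped to ``(x - rowMean) / rowSD`` so every eligible
    output row has mean 0 and (population) SD 1.  Rows with zero SD cannot
    be normalized; they are flagged rather than silently zeroed.

    Returns
    -------
    (z, eligible)
        ``z`` matches the input container type; ineligible rows are left
        as NaN.  ``eligible`` is a boolean array, one entry per gene.
    """
    X, ids, cols = _as_matrix(matrix)
    if X.shape[1] < 2:
        raise ValueError("z-score transform needs at least 2 samples")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    eligible = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mean) / sd
    Z[~eligible] = np.nan
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(Z, index=matrix.index, columns=matrix.columns), eligible
    return Z, eligible


def log2_fold_change(group1, group2, pseudocount=1.0):
    """log2 ratio of group means with a pseudocount.

    Computed on the original (nonnegative) expression scale; z-scores
    destroy ratios and counts may contain zeros, hence the pseudocount.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if np.any(g1 < 0) or np.any(g2 < 0):
        raise ValueError("fold change requires nonnegative expression values")
    return float(np.log2((g1.mean() + pseudocount) / (g2.mean() + pseudocount)))


def _t_matrix(X1, X2, beta, tol=1e-6, max_iter=100):
    """Vectorized robust t and Satterthwaite df for row-paired groups.

    ``X1``: (G, n1), ``X2``: (G, n2).  Returns (t, df, n_iter1, n_iter2).
    Degenerate rows: both scales zero with equal locations give t = 0;
    with unequal locations t saturates at +/-inf.
    """
    mu1, s21, w1, it1, _ = _fit_matrix(X1, beta, tol=tol, max_iter=max_iter)
    mu2, s22, w2, it2, _ = _fit_matrix(X2, beta, tol=tol, max_iter=max_iter)
    n1 = w1.sum(axis=1)
    n2 = w2.sum(axis=1)
    v1 = s21 / n1
    v2 = s22 / n2
    se2 = v1 + v2
    diff = mu1 - mu2

    t = np.empty_like(diff)
    df = np.ones_like(diff)
    degenerate = se2 <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t[~degenerate] = diff[~degenerate] / np.sqrt(se2[~degenerate])
        denom = (
            v1 ** 2 / np.maximum(n1 - 1.0, _SIGMA2_FLOOR)
            + v2 ** 2 / np.maximum(n2 - 1.0, _SIGMA2_FLOOR)
        )
        good = ~degenerate & (denom > 0)
        df[good] = se2[good] ** 2 / denom[good]
    df = np.clip(df, 1.0, None)
    # zero spread in both groups: equal locations -> t = 0, else saturated
    t[degenerate] = np.where(diff[degenerate] == 0, 0.0,
                             np.copysign(np.inf, diff[degenerate]))
    return t, df, it1, it2


def robust_t_statistic(group1, group2, beta=0.2, tol=1e-6, max_iter=100):
    """Robust two-sample t-statistic and Satterthwaite df for one gene.

    ``t = (mu1 - mu2) / sqrt(s1^2/n1~ + s2^2/n2~)`` with minimum
    beta-divergence location/scale estimates and effective sample sizes
    ``n_g~`` equal to the sum of the final beta-weights.

    Returns
    -------
    (t, df) : tuple of floats
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    t, df, _, _ = _t_matrix(g1[None, :], g2[None, :], beta, tol=tol, max_iter=max_iter)
    return float(t[0]), float(df[0])


def _two_group_masks(labels, columns=None):
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(
            f"expected exactly two distinct group labels, got {list(groups)}"
        )
    return labels == groups[0], labels == groups[1], groups


def robust_t_test(matrix, labels, beta=0.2, alpha=0.05, fc_threshold=1.5,
                  pseudocount=1.0, tol=1e-6, max_iter=100, bh_adjust=False):
    """Gene-wise robust differential-expression test.

    Applies the z-score transform, computes the robust t-statistic and a
    two-sided p-value per gene, the log2 fold change on the original scale,
    and assigns a regulation call: ``up`` when ``p < alpha`` and
    ``log2_fc >= fc_threshold``, ``down`` when ``p < alpha`` and
    ``log2_fc <= -fc_threshold``, otherwise ``not_significant``.

    Parameters
    ----------
    matrix : DataFrame or ndarray, genes x samples
        Nonnegative expression values on the original scale.
    labels : sequence, length n_samples
        Exactly two distinct group labels; the fold change and the sign of
        t refer to first-seen group minus the other.
    beta : float
        Robustness tuning parameter (0 recovers the classical test).
    alpha : float
        Significance level for the call.
    fc_threshold : float
        Threshold on the log2 scale.
    bh_adjust : bool
        If True an extra ``p_adjusted`` (Benjamini-Hochberg) column is
        added and used for calling; off by default.

    Returns
    -------
    DataFrame with columns gene_id, t, df, p_value, log2_fc, call, flags,
    n_iter_g1, n_iter_g2, in input gene order.  Genes failing z-score
    eligibility (constant rows) are kept, flagged ``zero_sd`` and called
    ``not_significant``.
    """
    X, gene_ids, _ = _as_matrix(matrix)
    m1, m2, groups = _two_group_masks(labels)
    if m1.size != X.shape[1]:
        raise ValueError("labels length does not match the number of samples")
    # fold change only makes sense on the original nonnegative scale; the
    # test itself (run on z-scores) accepts any real-valued matrix
    has_negative = bool(np.any(X < 0))

    Z, eligible = zscore_transform(X)
    G = X.shape[0]
    t = np.zeros(G)
    df = np.ones(G)
    p = np.ones(G)
    it1 = np.zeros(G, dtype=int)
    it2 = np.zeros(G, dtype=int)

    if eligible.any():
        Ze = Z[eligible]
        te, dfe, i1, i2 = _t_matrix(Ze[:, m1], Ze[:, m2], beta, tol=tol, max_iter=max_iter)
        saturated = np.isinf(te)
        pe = np.empty_like(te)
        pe[~saturated] = 2.0 * stats.t.sf(np.abs(te[~saturated]), dfe[~saturated])
        pe[saturated] = 0.0
        t[eligible] = te
        df[eligible] = dfe
        p[eligible] = pe
        it1[eligible] = i1
        it2[eligible] = i2

    if has_negative:
        log2_fc = np.full(G, np.nan)
    else:
        means1 = X[:, m1].mean(axis=1)
        means2 = X[:, m2].mean(axis=1)
        log2_fc = np.log2((means1 + pseudocount) / (means2 + pseudocount))

    flags = np.where(eligible, "", "zero_sd")
    flags = np.where(np.isinf(t), "saturated", flags)

    p_call = p
    result = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "t": t,
            "df": df,
            "p_value": p,
            "log2_fc": log2_fc,
            "n_iter_g1": it1,
            "n_iter_g2": it2,
            "flags": flags,
        }
    )
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        result["p_adjusted"] = multipletests(p, method="fdr_bh")[1]
        p_call = result["p_adjusted"].to_numpy()

    call = np.full(G, CALL_NS, dtype=object)
    sig = (p_call < alpha) & eligible
    call[sig & (log2_fc >= fc_threshold)] = CALL_UP
    call[sig & (log2_fc <= -fc_threshold)] = CALL_DOWN
    result["call"] = call
    cols = ["gene_id", "t", "df", "p_value"]
    if bh_adjust:
        cols.append("p_adjusted")
    cols += ["log2_fc", "call", "flags", "n_iter_g1", "n_iter_g2"]
    return result[cols].reset_index(drop=True)


def classical_t_test(matrix, labels, alpha=0.05, fc_threshold=1.5,
                     pseudocount=1.0, bh_adjust=False):
    """Classical Welch-style baseline: the robust test with beta = 0."""
    return robust_t_test(
        matrix,
        labels,
        beta=0.0,
        alpha=alpha,
        fc_threshold=fc_threshold,
        pseudocount=pseudocount,
        bh_adjust=bh_adjust,
    )


class RobustTTest(SelectorMixin, BaseEstimator):
    """Robust differential-expression test as a scikit-learn selector.

    Follows the ``fit(X, y)`` convention with ``X`` of shape
    ``(n_samples, n_genes)`` and ``y`` the two-group labels; as a
    :class:`~sklearn.feature_selection.SelectorMixin` its ``transform``
    keeps the genes called up- or down-regulated, so it composes with
    pipelines and model selection.

    Parameters
    ----------
    beta : float, default 0.2
    alpha : float, default 0.05
    fc_threshold : float, default 1.5
        On the log2 scale.
    pseudocount : float, default 1.0
    tol, max_iter : convergence controls of the inner estimator.

    Attributes
    ----------
    statistic_, df_, pvalues_, log2_fc_ : ndarrays of shape (n_genes,)
    calls_ : object ndarray with entries up / down / not_significant
    results_ : DataFrame, the full per-gene result table
    """

    def __init__(self, beta=0.2, alpha=0.05, fc_threshold=1.5, pseudocount=1.0,
                 tol=1e-6, max_iter=100):
        self.beta = beta
        self.alpha = alpha
        self.fc_threshold = fc_threshold
        self.pseudocount = pseudocount
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        res = robust_t_test(
            X.T,
            y,
            beta=self.beta,
            alpha=self.alpha,
            fc_threshold=self.fc_threshold,
            pseudocount=self.pseudocount,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.results_ = res
        self.statistic_ = res["t"].to_numpy()
        self.df_ = res["df"].to_numpy()
        self.pvalues_ = res["p_value"].to_numpy()
        self.log2_fc_ = res["log2_fc"].to_numpy()
        self.calls_ = res["call"].to_numpy()
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "calls_")
        return self.calls_ != CALL_NS
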