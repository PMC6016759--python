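"""Confusion-matrix metrics, ROC/AUC, and the replicate benchmark harness.

Two "AUC" notions coexist in the DE-benchmarking literature and both are
provided: ``balanced_auc = (TPR + TNR) / 2`` (the balanced accuracy of a
fixed calling rule) and the trapezoidal area under the ROC curve obtained
by sweeping the p-value ranking.  The benchmark report prints the ROC
version.  Empirical FDR here is the false discovery proportion
``FP / (TP + FP)`` of a fixed calling rule, not an adjusted quantity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .detest import classical_t_test, robust_t_test
from .simulate import contaminate, simulate_counts

__all__ = [
    "ConfusionMetrics",
    "confusion",
    "roc_points",
    "auc",
    "pauc",
    "BenchmarkConfig",
    "run_benchmark",
    "summarize_benchmark",
]

logger = logging.getLogger(__name__)

_METRIC_COLUMNS = ["sensitivity", "specificity", "fpr", "fnr", "fdr",
                   "mer", "acc", "ppv", "npv", "balanced_auc",
                   "roc_auc", "pauc"]


def _ratio(num, den):
    """num/den, or NaN (the undefined flag) when the denominator is zero."""
    return num / den if den > 0 else math.nan


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and the derived binary-classification measures.

    Positives are DE genes.  Ratios with a zero denominator are NaN,
    flagging them as undefined rather than silently zero.
    """

    n_tp: int
    n_fp: int
    n_tn: int
    n_fn: int

    @property
    def total(self):
        return self.n_tp + self.n_fp + self.n_tn + self.n_fn

    @property
    def sensitivity(self):  # TPR
        return _ratio(self.n_tp, self.n_tp + self.n_fn)

    @property
    def specificity(self):  # TNR
        return _ratio(self.n_tn, self.n_tn + self.n_fp)

    @property
    def fpr(self):
        return _ratio(self.n_fp, self.n_fp + self.n_tn)

    @property
    def fnr(self):
        return _ratio(self.n_fn, self.n_fn + self.n_tp)

    @property
    def fdr(self):
        return _ratio(self.n_fp, self.n_tp + self.n_fp)

    @property
    def mer(self):
        """Misclassification error rate (FP + FN) / total."""
        return _ratio(self.n_fp + self.n_fn, self.total)

    @property
    def acc(self):
        return _ratio(self.n_tp + self.n_tn, self.total)

    @property
    def ppv(self):
        return _ratio(self.n_tp, self.n_tp + self.n_fp)

    @property
    def npv(self):
        return _ratio(self.n_tn, self.n_tn + self.n_fn)

    @property
    def balanced_auc(self):
        """(TPR + TNR) / 2 — the fixed-threshold 'AUC' of a calling rule."""
        return (self.sensitivity + self.specificity) / 2.0

    def as_dict(self):
        d = {"n_tp": self.n_tp, "n_fp": self.n_fp,
             "n_tn": self.n_tn, "n_fn": self.n_fn}
        for name in ("sensitivity", "specificity", "fpr", "fnr", "fdr",
                     "mer", "acc", "ppv", "npv", "balanced_auc"):
            d[name] = getattr(self, name)
        return d


def confusion(truth, called):
    """Count the confusion matrix of DE/EE calls against ground truth.

    Parameters
    ----------
    truth, called : equal-length sequences with entries in {"DE", "EE"}

    Returns
    -------
    ConfusionMetrics
    """
    truth = np.asarray(truth)
    called = np.asarray(called)
    if truth.shape != called.shape:
        raise ValueError("truth and called must have equal length")
    valid = {"DE", "EE"}
    seen = set(np.unique(truth)) | set(np.unique(called))
    if not seen <= valid:
        raise ValueError(f"labels must be in {valid}, got {sorted(seen)}")
    t = truth == "DE"
    c = called == "DE"
    return ConfusionMetrics(
        n_tp=int(np.sum(t & c)),
        n_fp=int(np.sum(~t & c)),
        n_tn=int(np.sum(~t & ~c)),
        n_fn=int(np.sum(t & ~c)),
    )


def roc_points(scores, truth):
    """ROC curve of a per-gene ranking score against DE/EE truth.

    Larger scores rank as more likely DE (pass ``1 - p`` or ``-p`` for
    p-values).  Ties are collapsed into single steps; the curve starts at
    (0, 0), ends at (1, 1) and is monotone in both coordinates.

    Returns
    -------
    (fpr, tpr) : pair of ndarrays
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = truth == "DE"
    if y.all() or not y.any():
        raise ValueError("ROC is undefined when truth has a single class")
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    return fpr, tpr


def auc(points):
    """Trapezoidal area under an ROC curve given as (fpr, tpr)."""
    fpr, tpr = points
    return float(np.trapezoid(tpr, fpr))


def pauc(points, fpr_max=0.1):
    """Partial AUC over FPR in [0, fpr_max], unnormalized (so <= fpr_max)."""
    fpr, tpr = np.asarray(points[0]), np.asarray(points[1])
    if not 0 < fpr_max <= 1:
        raise ValueError("fpr_max must be in (0, 1]")
    keep = fpr < fpr_max
    t_at_max = float(np.interp(fpr_max, fpr, tpr))
    fx = np.append(fpr[keep], fpr_max)
    tx = np.append(tpr[keep], t_at_max)
    return float(np.trapezoid(tx, fx))


@dataclass(frozen=True)
class BenchmarkConfig:
    """Settings of the replicate outlier-contamination benchmark."""

    G: int = 1000
    n_de: int = 100
    n1: int = 3
    n2: int = 3
    nb_config: dict | None = None
    fc_config: dict | None = None
    magnitude_config: dict | None = None
    outlier_levels: tuple = (0.0, 0.05, 0.10, 0.15, 0.20)
    n_replicates: int = 50
    alpha: float = 0.05
    beta: float = 0.2
    pauc_fpr_max: float = 0.1
    methods: tuple = ("robust_t", "classical_t")
    seed: int = 0


def _method_pvalues(name, counts, labels, cfg, adapters):
    """Per-gene p-values of a named method; None if unavailable."""
    if name == "robust_t":
        return robust_t_test(counts, labels, beta=cfg.beta,
                             alpha=cfg.alpha)["p_value"].to_numpy()
    if name == "classical_t":
        return classical_t_test(counts, labels,
                                alpha=cfg.alpha)["p_value"].to_numpy()
    fn = (adapters or {}).get(name)
    if fn is None:
        return None
    return np.asarray(fn(counts, labels), dtype=float)


def _replicate_seed(master, level_index, replicate):
    # fixed-offset derivation, kept below 2**31 for portability
    return (int(master) * 1_000_003 + level_index * 1009 + replicate) % (2 ** 31)


def run_benchmark(config=None, adapters=None, **overrides):
    """Run the simulate -> contaminate -> test -> score benchmark grid.

    For every outlier level and replicate a fresh dataset is simulated and
    contaminated, each method produces per-gene p-values, genes with
    ``p < alpha`` are called DE, and confusion metrics plus ROC AUC / pAUC
    (genes ranked by ascending p-value) are recorded.

    Parameters
    ----------
    config : BenchmarkConfig, optional
        Keyword overrides may be passed directly instead.
    adapters : dict, optional
        Extra methods: name -> callable(counts_df, labels) -> p-value
        array.  An adapter raising an exception is skipped with a warning.

    Returns
    -------
    DataFrame in long format, one row per (method, outlier level,
    replicate) with confusion counts and every derived metric.
    """
    if config is None:
        config = BenchmarkConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config object or keyword overrides")

    rows = []
    for li, level in enumerate(config.outlier_levels):
        for rep in range(config.n_replicates):
            s = _replicate_seed(config.seed, li, rep)
            data = simulate_counts(
                G=config.G, n_de=config.n_de, n1=config.n1, n2=config.n2,
                nb_config=config.nb_config, fc_config=config.fc_config,
                seed=s,
            )
            data = contaminate(
                data, level, magnitude_config=config.magnitude_config,
                seed=s + 1,
            )
            for method in config.methods:
                try:
                    pvals = _method_pvalues(method, data.counts, data.labels,
                                            config, adapters)
                except Exception as exc:  # adapter failure is not fatal
                    logger.warning("method %r failed (%s); skipped", method, exc)
                    continue
                if pvals is None:
                    logger.warning("method %r unavailable; skipped", method)
                    continue
                called = np.where(pvals < config.alpha, "DE", "EE")
                cm = confusion(data.truth, called)
                pts = roc_points(1.0 - pvals, data.truth)
                row = {"method": method, "outlier_level": level,
                       "replicate": rep, "seed": s}
                row.update(cm.as_dict())
                row["roc_auc"] = auc(pts)
                row["pauc"] = pauc(pts, config.pauc_fpr_max)
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_benchmark(long_table):
    """Mean-over-replicates summary grid: metrics x methods per level."""
    means = (
        long_table
        .groupby(["outlier_level", "method"], sort=True)[_METRIC_COLUMNS]
        .mean()
        .reset_index()
    )
    grid = means.melt(
        id_vars=["outlier_level", "method"],
        var_name="metric", value_name="value",
    ).pivot_table(
        index=["outlier_level", "metric"], columns="method", values="value",
        sort=False,
    ).reset_index()
    grid.columns.name = None
    return grid
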