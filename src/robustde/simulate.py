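"""Two-group negative-binomial count simulator with outlier contamination.

Generates gene-by-sample count matrices with known ground truth for
benchmarking differential-expression callers.  Each gene draws counts from
a negative binomial whose per-gene baseline mean is log-uniform on
[20, 2000] and whose dispersion (1/size) is uniform on [0.05, 0.4] —
typical bulk RNA-seq ranges.  A configurable block of DE genes has the
second group's mean multiplied (or divided, alternating so up- and
down-regulation are balanced) by a fold change drawn uniform on [2, 4].

Contamination replaces one randomly chosen cell in a chosen fraction of
genes by its value times a factor uniform on [5, 10] — the single-cell
multiplicative spike convention of DE robustness studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SimulatedDataset", "simulate_counts", "contaminate",
           "DEFAULT_NB_CONFIG", "DEFAULT_FC_CONFIG", "DEFAULT_MAGNITUDE_CONFIG"]

DEFAULT_NB_CONFIG = {"mean_low": 20.0, "mean_high": 2000.0,
                     "disp_low": 0.05, "disp_high": 0.4}
DEFAULT_FC_CONFIG = {"fc_low": 2.0, "fc_high": 4.0}
DEFAULT_MAGNITUDE_CONFIG = {"factor_low": 5.0, "factor_high": 10.0}

GROUP1 = "healthy"
GROUP2 = "disease"


@dataclass(frozen=True)
class SimulatedDataset:
    """A simulated two-group count matrix with ground truth.

    Attributes
    ----------
    counts : DataFrame, genes x samples, nonnegative integers
    labels : ndarray of sample group labels (two groups)
    truth : ndarray of per-gene labels in {"DE", "EE"}
    outlier_mask : boolean ndarray, genes x samples
    params : dict, the full generator parameter record including the seed
    """

    counts: pd.DataFrame
    labels: np.ndarray
    truth: np.ndarray
    outlier_mask: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_genes(self):
        return self.counts.shape[0]

    @property
    def n_samples(self):
        return self.counts.shape[1]


def simulate_counts(G=1000, n_de=100, n1=3, n2=3, nb_config=None,
                    fc_config=None, seed=None):
    """Draw a two-group negative-binomial count matrix with ground truth.

    Parameters
    ----------
    G : int
        Number of genes.
    n_de : int
        Number of truly differentially expressed genes (the first ``n_de``
        rows); the remaining ``G - n_de`` genes are equally expressed.
    n1, n2 : int >= 2
        Samples per group.
    nb_config : dict, optional
        Keys mean_low/mean_high (log-uniform baseline mean range) and
        disp_low/disp_high (uniform dispersion range, dispersion = 1/size).
    fc_config : dict, optional
        Keys fc_low/fc_high; DE fold changes are uniform in this range and
        applied to group 2, alternately multiplying and dividing.
    seed : int, optional
        Identical parameters + seed give a bit-identical dataset.

    Returns
    -------
    SimulatedDataset with an all-false outlier mask.
    """
    if not 0 <= n_de <= G:
        raise ValueError("n_de must satisfy 0 <= n_de <= G")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    nb = {**DEFAULT_NB_CONFIG, **(nb_config or {})}
    fc = {**DEFAULT_FC_CONFIG, **(fc_config or {})}

    rng = np.random.default_rng(seed)
    base_mean = np.exp(rng.uniform(np.log(nb["mean_low"]), np.log(nb["mean_high"]), G))
    dispersion = rng.uniform(nb["disp_low"], nb["disp_high"], G)
    size = 1.0 / dispersion  # NB "number of failures" parameter

    fold = np.ones(G)
    de_fc = rng.uniform(fc["fc_low"], fc["fc_high"], n_de)
    direction = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    fold[:n_de] = np.where(direction > 0, de_fc, 1.0 / de_fc)

    mean1 = base_mean
    mean2 = base_mean * fold

    def draw(mean, n):
        p = size[:, None] / (size[:, None] + mean[:, None])
        return rng.negative_binomial(size[:, None], p, size=(G, n))

    counts = np.hstack([draw(mean1, n1), draw(mean2, n2)])
    truth = np.array(["DE"] * n_de + ["EE"] * (G - n_de))
    labels = np.array([GROUP1] * n1 + [GROUP2] * n2)
    gene_ids = [f"gene_{i + 1:05d}" for i in range(G)]
    sample_ids = [f"{GROUP1}_{j + 1}" for j in range(n1)] + \
                 [f"{GROUP2}_{j + 1}" for j in range(n2)]
    frame = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    params = {
        "G": G, "n_de": n_de, "n1": n1, "n2": n2,
        "nb_config": nb, "fc_config": fc, "seed": seed,
        "outlier_fraction": 0.0, "magnitude_config": None,
    }
    return SimulatedDataset(
        counts=frame,
        labels=labels,
        truth=truth,
        outlier_mask=np.zeros((G, n1 + n2), dtype=bool),
        params=params,
    )


def contaminate(data, outlier_fraction, magnitude_config=None, seed=None):
    """Corrupt a fraction of genes with a single multiplicative outlier cell.

    ``round(outlier_fraction * G)`` genes are chosen uniformly at random;
    in each, one randomly chosen cell is multiplied by a factor drawn
    uniform from ``magnitude_config`` and rounded back to an integer.
    Truth labels are unchanged; the outlier mask records the spiked cells.

    Returns a new SimulatedDataset; ``outlier_fraction = 0`` returns the
    input dataset unchanged.
    """
    if not 0.0 <= outlier_fraction <= 1.0:
        raise ValueError("outlier_fraction must be in [0, 1]")
    if outlier_fraction == 0.0:
        return data
    mag = {**DEFAULT_MAGNITUDE_CONFIG, **(magnitude_config or {})}
    G, n = data.counts.shape
    n_out = int(round(outlier_fraction * G))

    rng = np.random.default_rng(seed)
    genes = rng.choice(G, size=n_out, replace=False)
    cells = rng.integers(0, n, size=n_out)
    factors = rng.uniform(mag["factor_low"], mag["factor_high"], n_out)

    counts = data.counts.to_numpy().copy()
    mask = data.outlier_mask.copy()
    counts[genes, cells] = np.rint(counts[genes, cells] * factors).astype(counts.dtype)
    mask[genes, cells] = True
    frame = pd.DataFrame(counts, index=data.counts.index, columns=data.counts.columns)
    params = {**data.params, "outlier_fraction": outlier_fraction,
              "magnitude_config": mag, "contaminate_seed": seed}
    return replace(data, counts=frame, outlier_mask=mask, params=params)
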