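# robustde

Outlier-robust differential expression (DE) testing for two-group
expression count data, built around the **minimum β-divergence** family of
robust estimators, together with the negative-binomial simulator and the
confusion-matrix/ROC harness needed to benchmark DE callers under
controlled outlier contamination.

It is aimed at transcriptomics analysts who need a two-group DE screen
(bulk or single-cell count matrices, or microarray intensities) that does
not let a handful of aberrant cells drive the gene list, and at
methodologists who want a reproducible contamination benchmark.

## The statistic

The two-sample t-statistic depends on per-group means and variances, and
the classical estimators of both are unbounded in a single observation.
Here they are replaced by the minimum β-divergence (density-power
divergence) estimators, defined through the **β-weight**

```
w_i = exp( −β (x_i − μ)² / (2σ²) )
```

and the fixed-point iteration

```
μ   ← Σ w_i x_i / Σ w_i
σ²  ← (1+β) Σ w_i (x_i − μ)² / Σ w_i
```

which exponentially downweights observations far from the bulk; β → 0
recovers the sample mean and the maximum-likelihood variance. The robust
t-statistic for gene *g* is then

```
t_g = (μ̂₁ − μ̂₂) / sqrt( σ̂₁²/ñ₁ + σ̂₂²/ñ₂ ),    ñ_g = Σ w_i (group g)
```

with Welch–Satterthwaite degrees of freedom computed from the same
quantities and two-sided p-values from the t distribution. Genes are
z-score normalized per row before testing; up/down regulation calls
combine `p < α` with a log2 fold-change threshold (default 1.5) computed
on the original count scale. Defaults: β = 0.2, α = 0.05.

## Worked example

```python
import numpy as np
from robustde import simulate_counts, contaminate, robust_t_test, classical_t_test

data = simulate_counts(G=1000, n_de=100, n1=3, n2=3, seed=1)   # NB counts + truth
data = contaminate(data, 0.20, seed=2)            # spike one cell in 20% of genes

res = robust_t_test(data.counts, data.labels, beta=0.2)
print((res.p_value < 0.05).sum())                 # genes called DE at p < 0.05
print(res.loc[res.p_value < 0.05].head(3)[["gene_id", "t", "p_value", "log2_fc"]])
```

Output:

```
114
      gene_id          t   p_value   log2_fc
3  gene_00004   6.329158  0.032812  1.438566
6  gene_00007 -12.189970  0.008788 -0.161403
7  gene_00008  62.168743  0.000800  1.601680
```

114 of 1000 genes fall below p = 0.05; `t` is the robust statistic and
`log2_fc` the log2 ratio of group means (healthy over disease), so
`gene_00008` is up-regulated roughly 3-fold. `gene_00007` shows a large
|t| but a near-zero fold change — its regulation `call` therefore stays
`not_significant`, since calls require both `p < α` and
`|log2_fc| ≥ 1.5`. The same
analysis with `classical_t_test` (β = 0) provides the non-robust Welch
baseline, and `run_benchmark` scores both against the simulator's ground
truth (sensitivity, specificity, FDR, MER, ROC AUC, pAUC, …) over
replicates and contamination levels.

A scikit-learn interface is available for pipeline composition:
`RobustTTest().fit(X, y)` with `X` of shape (samples × genes) acts as a
feature selector keeping the called genes, and `BetaGaussianEstimator`
exposes the column-wise robust location/scale fit.

## Command line

```
robustde simulate  -G 1000 --n-de 100 --outlier-fraction 0.2 --seed 1 --out-prefix sim
robustde test      sim_counts.tsv sim_labels.tsv -o results.tsv
robustde benchmark --config config.yaml -o benchmark.tsv
robustde select-beta sim_counts.tsv sim_labels.tsv --grid 0,0.1,0.2,0.3,0.4
```

Count matrices are plain TSV/CSV (gene IDs in the first column, sample IDs
in the header); labels are a two-column `sample_id<TAB>group` table. All
randomness is seed-controlled and outputs are byte-identical across reruns
of the same config + seed.

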