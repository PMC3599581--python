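# plsstab — stable PLS-based multiclass gene selection

`plsstab` selects small, *stable* marker-gene panels from multiclass
expression data (bulk microarray or any samples × genes matrix) and
quantifies both how well the selected genes classify and how reproducible
the selected list is under resampling. It is aimed at anyone who needs a
short ranked gene list that survives a slightly different cohort — e.g.
for RT-qPCR follow-up — rather than a list that merely maximizes one
accuracy number.

## Method

**Ranking.** Genes are ranked by squared partial-least-squares (PLS)
weights. For a column-centered matrix `X` (l samples × m genes) and a
coded response `y`, each PLS weight vector solves

    w_i = argmax_{wᵀw = 1} cov²(Xw, y),     w_iᵀ XᵀX w_j = 0  (j < i)

and the importance of gene *j* is `Σ_{i≤s} w_ij²` over the first `s`
components. Two algorithms are provided: NIPALS (weights `w_i` on the
deflated matrix) and SIMPLS (weights `r_i` applicable to the original
matrix); for one component they coincide.

**Multiclass decomposition.** A K-class problem is solved either all at
once (`mclass`: one fit against the l × K ±1 class-indicator matrix) or
decomposed into two-class sub-problems — one-vs-rest (`ovr`, K problems)
or one-vs-one (`ovo`, K(K−1)/2 problems), with `y = ±1` coding. The
per-problem rankings are merged round-robin: every problem's best gene
first, then every problem's next not-yet-listed gene, and so on.
Baselines: pooled-variance t-statistic and linear SVM recursive feature
elimination (RFE), decomposed and merged the same way.

**Error estimation.** A *balanced* bootstrap (each sample appears exactly
B times across the B resamples) drives the .632+ estimator

    Err^(.632+) = 0.368·Err_resub + 0.632·Err_test + overfitting correction,

where the correction is controlled by the relative overfitting rate
`R̂ = (Err_test − Err_resub)/(γ̂ − Err_resub)` and the no-information rate
`γ̂ = Σ_k p̂_k(1 − q̂_k)`. Selection is redone inside every bootstrap
iteration, so the error estimate covers the whole selection+classification
pipeline. Classifiers: linear SVM (OvO, OvR, Crammer–Singer multiclass)
and shrinkage LDA.

**Stability.** The whole-data top-g list L is compared against the B
bootstrap lists L_b by: `s1` (fraction of overlapping genes), `s2`
(rank-displacement index, absent genes placed at g+1), per-gene
bootstrap-based feature-ranking scores Q (mean rank credit) and Q′
(selection frequency), and the reselected-gene count (distinct genes ever
selected; ideal value g).

## Worked example

```python
from plsstab import (SyntheticSpec, generate, ExperimentConfig,
                     SelectorSpec, run_experiment)

# 3 classes, 20 samples/class, 1000 genes, 30 planted markers (delta = 2*sigma)
dataset, markers = generate(SyntheticSpec(seed=1))

config = ExperimentConfig(
    selectors=(SelectorSpec(selector="pls", mode="ovo",
                            algo="simpls", components=1),),
    classifiers=("svm_ovo", "lda"),
    B=50, g_max=30, g_stability=30, seed=1,
)
result = run_experiment(dataset, config)
print(result.table[["method", "s1", "s2", "reselected", "acc", "accL", "accH"]]
      .to_string(index=False))
```

prints

```
            method   s1    s2  reselected  acc  accL  accH
SIMPLS+OVO 1 comp. 0.94 0.828          71  1.0   1.0   1.0
```

meaning: across 50 bootstrap iterations the 30-gene lists share 94% of
their genes with the whole-data list (`s1`), keep their ordering well
(`s2 = 0.83`), and only 71 distinct genes were ever selected (ideal 30);
the best .632+ accuracy over list lengths 1..30 is 1.0 (the planted
effect is strong), with the 95% percentile interval of per-iteration
out-of-bag accuracies [1.0, 1.0].

The same pipeline is scriptable from a shell:

```sh
plsstab --seed 1 simulate --out-matrix m.tsv --out-labels y.tsv
plsstab rank --matrix m.tsv --labels y.tsv --mode ovo --top 30 --out list.tsv
plsstab evaluate --config experiment.yaml --out-dir results/
```

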