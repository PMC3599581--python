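# Methods

This note documents the models and procedures `plsstab` implements, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## PLS weight-vector ranking

Both PLS algorithms operate on a column-centered matrix; **no
unit-variance scaling is applied by default** (an opt-in exists at the
caller level by standardizing before construction). Centering-only is
deliberate: squared first-component weights then order genes by squared
covariance with the coded response, whereas on unit-variance data the
same order coincides with the F-statistic (equal-variance t-test) order —
both behaviors are covered by tests.

* **NIPALS.** The univariate weight is closed-form per component
  (`w ∝ X_dᵀ y_d`, unit norm); X **and** the response are deflated after
  each component (classical NIPALS). For a multivariate response the
  inner loop iterates to a relative weight change below 1e−10, capped at
  500 iterations.
* **SIMPLS.** Weights `r_i` apply to the original centered matrix
  (`T = X R` by construction); orthogonality is enforced by projecting
  the cross-product matrix off the span of the previous x-loadings.
* **Conventions.** All weight columns have unit norm, so summed squared
  weights are comparable across components; each column's sign is fixed
  (largest-magnitude entry positive) to make fits byte-reproducible. Sign
  and per-component scale are mathematical conventions: for a univariate
  response the two algorithms produce identical score *directions*, while
  raw score norms depend on the normalization convention, so cross-
  algorithm comparisons are made on unit-normalized, sign-aligned columns.
* **Weight conversion.** NIPALS weights are mapped to original-matrix
  weights by the triangular solve `R = W (PᵀW)^{-1}`. The per-component
  scalar shortcut `r_i = w_i / (p_iᵀw_i)` is degenerate under the unit-
  norm convention (`p_iᵀw_i = 1` identically, giving `r_i = w_i`) and is
  not used; the matrix form reproduces the score matrix exactly and
  yields genuinely different directions for components beyond the first.
* **Degenerate inputs.** Requesting more components than the centered
  matrix's rank is an error (never silent truncation); a component whose
  score norm falls below 1e−12·‖X‖ stops fitting early with a warning; a
  zero-variance response is an error.

## Decomposition and list merging

OvR sublists are ordered by class 1..K, OvO by lexicographic pair order.
The merge is a round-robin over sublists in that fixed order, each
sublist contributing its next not-yet-emitted gene per round — so rank-1
genes of all problems come first, then the next available gene of each
problem, until `g` unique genes are collected. Ties in importance are
broken by ascending gene index (stable sort). These orderings are
conventions chosen once for reproducibility; the merged *set* is largely
insensitive to them.

The third-party "GS" style of selector is supported as a plug-in: any
function mapping a two-class problem (plus its expression submatrix) to
per-gene scores can be decomposed and merged identically
(`rank_custom` / `SelectorSpec(selector="custom", score_fn=...)`).

**RFE.** The elimination loop drops the lowest squared-coefficient 10% of
remaining genes per linear-SVM refit (at least one gene; C = 1), stopping
when the requested list length remains; survivors are ordered by the
final fit's coefficients, eliminated genes by reverse elimination order.
The loop is written here because a total gene order (including
within-batch order) is part of the list contract; the SVM solver is
scikit-learn's.

## Balanced bootstrap and .632+

A plan concatenates B copies of the l sample indices, permutes them, and
chunks by l, so each sample occurs exactly B times across the B training
multisets. If a chunk happens to cover every sample (empty out-of-bag
set) the **whole permutation** is redrawn — patching single chunks would
break the exact balance — with failure only plausible for very small l.
One plan is generated per experiment and shared by every selection method
and classifier so methods are compared on identical resamples.

The .632+ estimate uses Efron & Tibshirani's additive-correction form:

    Err632+ = 0.368·resub + 0.632·test + (test′ − resub)·0.368·0.632·R̂ / (1 − 0.368·R̂)

with `test′ = min(test, γ̂)` and `R̂ = (test′ − resub)/(γ̂ − resub)` set to
0 whenever `test′ ≤ resub` or `γ̂ ≤ resub` and clamped to [0, 1]. The
clamps and the `min(test, γ̂)` guard are required for the estimate to stay
in [0, 1] when γ̂ falls below the resubstitution error; with `R̂ = 0` the
formula is exactly the .632 estimator, and `resub = test` is a fixed
point for any γ̂. γ̂ is computed from the resubstitution predictions of
the same fitted model.

The 95% confidence interval on accuracy is the 2.5th–97.5th percentile
interval of the per-iteration out-of-bag accuracies at the best gene
count; because the point estimate blends in resubstitution accuracy it
can in principle exceed the percentile band, so the reported bounds are
widened to include it when necessary.

## Stability indices

`s1` and `s2` follow their definitions exactly; genes absent from a
bootstrap top-g list are placed at `g + 1` for `s2` and credited `r = 0`
for the Q score (consistent with `r = g − u + 1` evaluated at `u = g+1`).
`s2` is clamped at 0: the raw displacement sum can marginally exceed its
disjoint-lists normalizer `B·g(g+1)/2` for pathological orderings (a late
reference gene top-ranked in a bootstrap list whose earlier genes are all
absent), and the index is defined on a [0, 1] scale. The reselected-gene
count is bounded by `min(G, B·g)`, the attainable maximum for G total
genes. Note `s1 ≥ s2` is *not* an identity and is never asserted.

## Classifiers

Linear kernel, C = 1 for all SVM variants (pairwise = libsvm's native
OvO; one-vs-rest via a binary-SVM wrapper; the multiclass single-objective
machine is the Crammer–Singer formulation with a fixed solver seed). LDA
uses the `lsqr` solver with automatic shrinkage because the gene count
can approach the training count, where the pooled covariance is singular.
Features are centered with training-set means, re-applied at prediction.
An all-constant training matrix falls back to the majority class and the
fit is flagged `degenerate` rather than crashing.

## Experiment pipeline

Per bootstrap iteration, selection runs **only** on the training multiset
(repeated rows included); classifiers are trained on the top-g genes for
every g = 1..`g_max` and scored on the out-of-bag samples. The reported
"best" accuracy per classifier is the maximum .632+ accuracy over
g ≤ `g_max`; the full accuracy-vs-g curve is retained so any other
aggregation is recoverable. Stability is computed on the
`g_stability`-gene lists. Gene preselection (a variance-rank filter) is
available but **off by default**; when enabled it, too, is recomputed
inside every iteration. Parallel execution is an order-preserving map
with per-task seeds derived from the master seed before dispatch, so
results are identical for any worker count.

Default layout follows the study design this package targets: B = 500
bootstrap iterations and gene lists up to 30 genes. The test suite and
the acceptance script run scaled-down instances (B = 20–50, up to 1000
genes, 45–60 samples) chosen so every stage still exercises its full code
path.

## Synthetic data

The generator plants two marker kinds among Gaussian noise genes
(baseline 7, σ = 1 on a log-intensity-like scale): *pairwise* markers
(+δ in one class of a pair, −δ in the other) that only OvO-style
contrasts see at full strength, and *one-vs-rest* markers (+δ in a single
class). Defaults — K = 3, 20 samples/class, m = 1000, 5 markers per pair
and per class, δ = 2σ — give planted two-sample t values around 6–13
versus a null maximum near 3.5 over 1000 genes, i.e. strong but not
trivial signal. Marker columns are placed at random positions.

What passing tests on this generator establish: the ranking machinery
recovers known discriminative genes, decomposition modes behave as
designed, the error estimator sits at chance on pure noise, and stability
indices respond to component count. What they do not establish: behavior
under inter-gene correlation, batch effects, heavy-tailed noise or
probe-level artifacts — real microarray properties the generator
deliberately omits.

## Known limitations

* PLS here is a ranking device only; no regression prediction for new
  samples, kernel or sparse variants.
* The t-statistic assigns 0 to zero-pooled-variance genes, ranking
  constant genes last rather than erroring.
* The balanced bootstrap needs l ≥ 5 or so before non-empty out-of-bag
  sets are reliably achievable; tiny l with large B can exhaust the
  100 redraw attempts and error out.
* Stability indices compare lists of at least length g; shorter lists are
  rejected rather than padded.
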