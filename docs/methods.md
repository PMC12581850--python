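# Methods

## Model

Three nonnegative feature blocks `X_I` (`n × q_I`, I = 1 image, 2 gene,
3 pathway) over one patient cohort are factorized jointly as `X_I ≈ W H_I`
with one shared basis `W ≥ 0` (`n × K`) and per-modality coefficients
`H_I ≥ 0` (`K × q_I`). The fitted objective is

```
J(W, H) = Σ_I ( ‖X_I − W H_I‖²_F + (β/2) ‖H_I H_Iᵀ − M‖²_F ) + α ‖W − R‖²_F
```

- `α ≥ 0` weighs the network-regularization term that pulls `W` toward the
  prior `R` distilled from the fused patient-similarity network
  (semi-supervision by the recurrence task).
- `β ≥ 0` weighs the orthogonality penalty that drives distinct rows of
  each `H_I` apart, sparsifying co-modules. `M` is either the `K × K`
  identity (default: penalize row cross-products and pull row norms to 1)
  or the all-ones matrix (`ortho_target="ones"`: pull all entries of
  `H Hᵀ` toward 1); both targets are supported and tested.

**Orthogonality-penalty scale.** The penalty enters with weight `β/2`, not
`β`. This is deliberate: with this scale the multiplicative update rules
below are the *exact* KKT fixed-point iterations of `J` (its gradient in
`H_I` is `−2WᵀX_I + 2WᵀWH_I + 2β(H_IH_Iᵀ − M)H_I`), and the monotone-descent
guarantee holds. Pairing the same updates with a full-`β` penalty makes the
"objective" a different function than the one the updates descend, and it
measurably increases on hard instances. Since `β` is a free hyperparameter
swept over a grid, the convention only relabels the grid; it changes no
fitted model.

## Updates

Minimization alternates one multiplicative sweep over `W` then each `H_I`
(using the freshly updated `W`):

```
W   ← W  ∘ (Σ_I X_I H_Iᵀ + αR) / (Σ_I W H_I H_Iᵀ + αW + δ)
H_I ← H_I ∘ (Wᵀ X_I + β M H_I) / (WᵀW H_I + β H_I H_Iᵀ H_I + δ)
```

with guard `δ = 1e−10`. The `H` rule is written in its nonnegative-split
arrangement: the `−βMH_I` part of the gradient sits in the numerator and the
`+βH_IH_IᵀH_I` part in the denominator, so every denominator is strictly
positive for nonnegative factors and no flooring of negative entries is ever
needed. Keeping the full signed term `β(H_IH_Iᵀ − M)H_I` in the denominator
is algebraically equivalent at fixed points but can go negative at large
`β`; floored variants of that arrangement blow up the objective by tens of
orders of magnitude, which is why the split form is used. At
`α = β = 0` both rules reduce bitwise to the classical Lee–Seung joint-NMF
updates (`variant="jnmf"`); `oc_jnmf` keeps only `β`, `snf_jnmf` only `α`.

The objective is non-increasing under these updates; the test suite verifies
this to relative tolerance 1e−9 over 200 iterations for every variant, both
orthogonality targets and all 16 grid combinations
`α, β ∈ {0.01, 0.1, 1, 10}`, each on its own seeded instance (n = 60,
q = (30, 40, 50), K ∈ {5, 10}); the observed worst per-iteration change is
a strict decrease (≈ −1e−5).

**Initialization** is NNDSVD (nonnegative double SVD, zero-fill variant)
on the column-concatenation `[X_1 X_2 X_3]`, with structural zeros replaced
by a floor of 1e−6 so multiplicative updates can move them. This makes every
fit deterministic; reruns are bitwise-identical.

**Stopping.** Iterations stop when the relative objective change falls
below `tol` (default 1e−6) or at `max_iter` (default 500). The trace records
the objective, the relative error, and Frobenius distances between
successive `W` and `H_I` iterates.

**Block scaling.** Before fitting, each feature column is divided by its
maximum (into [0, 1]) so no modality dominates the Frobenius terms. Dividing
by the maximum (rather than min-max shifting) keeps zero at zero, so the
nonnegative rank of the data is preserved and an exact low-rank plant stays
exactly fittable. Scaling is on by default (`scale_blocks`) and the relative
error is always reported on the matrices actually fitted.

**Relative error** (the model-selection criterion) is, per block, the
column-means of `|X_I − W H_I|` divided by the block grand mean, averaged
over columns, summed over the three blocks. It is invariant to a joint
rescaling of the data and the reconstruction.

## The similarity prior

1. Per modality, pairwise Euclidean distances `D` between patient rows
   (the metric is a modeling choice; features should be on comparable
   scales, which the raw blocks of this pipeline are after scaling).
2. Scaled-exponential kernel `S_ij = exp(−D_ij²/(μ σ_ij))` with local
   bandwidth `σ_ij = (m_i + m_j + D_ij)/3`, `m_i` the mean distance of
   sample i to its k nearest neighbors; `μ = 0.5` by default. This is the
   canonical SNF kernel; it adapts to heterogeneous densities.
3. Row-stochastic k-NN affinity: neighbors get total mass `1 − ε`
   (proportional to similarity), non-neighbors share `ε` (default 0.01);
   self is excluded from both sets, ties at the k-th neighbor break toward
   the smaller sample index, and a row with no out-of-neighborhood mass
   folds `ε` back into its neighborhood. `k` defaults to ⌈n/10⌉.
4. Fusion is the convex combination `A = Σ_m w_m A^(m)` with uniform
   weights by default. (Iterative cross-diffusion is intentionally not
   used: the single weighted average is the model's definition here.)
5. Diagnostic: 2-way spectral clustering of `(A + Aᵀ)/2`, reported as the
   adjusted Rand index against the recurrence label. It never alters the
   pipeline.
6. Prior: column-center `A`, take the K leading principal-component score
   vectors, flip each component's sign so its largest-magnitude loading is
   positive (a deterministic convention), and min-max rescale each score
   column into [0, 1]. PCA scores are signed, but `R` must be nonnegative
   to sit in a multiplicative numerator; per-column min-max rescaling
   preserves the patient ordering within each component, which is the
   information `α‖W − R‖²` actually transfers. The scaling bounds are
   stored with the prior for reproducibility.

## Co-module evaluation

- **Feature selection**: component k selects features with
  `H_kj > mean(H_k·) + T·sd(H_k·)` (population SD, default `T = 1.5`).
  The rule is deliberately simple and monotone in `T`.
- **Clinical association**: Pearson r and two-sided p between each `W`
  column and each numeric clinical variable; the recurrence module is the
  column with the largest |r| against the label among p < 0.05 columns.
- **Differential screening**: per-feature two-sided Mann–Whitney test
  between label groups, normal approximation with tie correction and no
  continuity correction (so the test's p equals the closed-form
  rank-statistic expression exactly); raw p thresholds 0.01/0.05 follow the
  screening convention, with Benjamini–Hochberg q-values reported alongside.
- **Enrichment**: one-sided hypergeometric p per gene set against an
  explicit background universe, BH-corrected within the collection;
  enriched = q < 0.05.
- **Overlap ratio** `O = |enriched ∩ selected pathways| / |enriched|`,
  reported as missing (not 0) when nothing is enriched, so empty modules
  are not silently penalized.
- **ROC/AUC**: rank (Mann–Whitney) AUC with a DeLong placement-value 95%
  interval, clipped to [0, 1].

## Synthetic cohorts

The generator plants a ground truth that mirrors the structure (not the
content) of a tri-modal tumor cohort: a nonnegative basis `W*` whose
non-label components vary continuously across patients (uniform [0.1, 1])
while the designated label component is elevated by `label_strength`
(default 1.0) in a random half of the cohort on a [0.05, 0.25] baseline;
sparse coefficient rows with disjoint planted modules of `module_size`
features (loadings in [0.8, 1.2]) over a [0, 0.05] background; data
`X_I = W*H*_I + N(0, σ²)` clipped at zero (default σ = 0.1); the binary
label is the median threshold of the label component's column, giving a
balanced split; and a toy GMT in which each planted pathway feature's set
holds that component's planted genes plus a few decoy genes, next to
pure-decoy sets. Defaults: n = 100, q = (50, 80, 60), K* = 4,
module_size = 10.

What it does **not** emulate: count-like (Poisson/negative-binomial) noise,
feature-feature correlation beyond the shared basis, batch structure,
unbalanced cohorts, or survival-time outcomes. Passing recovery tests shows
the estimator finds planted low-rank cross-modal structure under Gaussian
noise; it does not certify performance on real pathology/expression data.

## Numerical choices and degenerate inputs

- denominator guard 1e−10; NNDSVD zero floor 1e−6.
- all-zero feature columns are dropped at load time with a warning
  (multiplicative updates cannot move them and they break correlations).
- constant rows/variables yield NaN correlations, flagged and excluded from
  summaries rather than erroring the whole run.
- neighbor ties break toward the smaller sample index; grid-search ties
  break toward smaller K, then α, then β.
- identical-sample cohorts (all-zero distance matrices) are rejected as
  degenerate before kernel computation.
- requesting K above the numerical rank of the concatenated data seeds the
  trailing components at the NNDSVD floor with a warning.

## Problem sizes

The test suite and the reproduction script run at desk scale, chosen so the
complete suite finishes in seconds on one CPU: monotonicity instances use
n = 60, q = (30, 40, 50) for 200 iterations; recovery uses n = 100,
q = (50, 80, 60) for 500 iterations; the 64-combination hyperparameter grid
runs at n = 40, q = (20, 25, 30) with 60 iterations per fit. These sizes are
the package's own demonstration conditions; the algorithms are dense-matrix
O(nKΣq_I) per iteration and scale to cohorts of hundreds of patients and
thousands of features without modification.

## Known limitations

- The fusion step is a single weighted average of affinities; learned or
  data-driven fusion weights are out of scope.
- The orthogonality penalty makes the subproblem non-convex quartic; the
  monotone-descent guarantee is to a stationary point, not a global
  optimum, and component recovery is only up to permutation and scale.
- The DeLong interval assumes independent samples; clustered or paired
  designs need a different variance estimator.
- Enrichment treats gene sets as unordered and ignores gene-gene
  dependence, as hypergeometric screening always does.
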