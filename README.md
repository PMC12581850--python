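# jsnmf

Joint similarity nonnegative matrix factorization for tri-modal tumor
cohorts: find latent **co-modules** — groups of pathology-image features,
genes and pathways that vary together across patients — and screen them for
association with local disease recurrence.

## The problem

Postoperative tumor recurrence is driven jointly by cellular morphology and
molecular state, but the three data types that capture them — patient-level
features aggregated from whole-slide images, gene expression, and per-sample
pathway activity scores — are usually analyzed in isolation. `jsnmf` fuses
them: given three nonnegative matrices `X_I` (`n` patients × `q_I` features,
`I = 1, 2, 3`) over one cohort with a binary recurrence label, it seeks a
shared nonnegative basis `W` (`n × K`) and per-modality coefficients `H_I`
(`K × q_I`) with

```
X_I ≈ W H_I ,   W ≥ 0, H_I ≥ 0 .
```

Each column of `W` scores every patient on one latent component; the
strongly loading features of `H_1, H_2, H_3` for that component form one
cross-modal co-module.

## The model

The factorization is anchored by a task-aware prior. Per modality, pairwise
Euclidean distances between patients are converted to a scaled-exponential
similarity kernel with local bandwidth, sharpened into a row-stochastic
k-nearest-neighbor affinity (mass `1−ε` inside each neighborhood), and the
three affinities are averaged into one fused network `A` (similarity network
fusion). Two-way spectral clustering of `A` against the recurrence label is
reported as a sanity check, and the `n × K` prior `R = PCA(A, K)` (score
columns rescaled into [0, 1]) enters the objective

```
J(W, H) = Σ_I ( ‖X_I − W H_I‖²_F + (β/2) ‖H_I H_Iᵀ − M‖²_F ) + α ‖W − R‖²_F
```

with `M` the identity (or all-ones) `K × K` target. `α` pulls patient
scores toward the fused-network geometry (semi-supervision); `β` pushes the
rows of each `H_I` toward orthogonality, which sparsifies the co-modules.
Minimization uses NNDSVD-initialized multiplicative updates

```
W   ← W  ∘ (Σ_I X_I H_Iᵀ + αR) / (Σ_I W H_I H_Iᵀ + αW)
H_I ← H_I ∘ (Wᵀ X_I + βM H_I) / (WᵀW H_I + β H_I H_Iᵀ H_I)
```

which are the exact KKT fixed-point rules of `J`, keep all factors
nonnegative, and never increase `J` (verified across the full
hyperparameter grid by the test suite). Everything is deterministic: no
random initialization anywhere.

Downstream, the co-module most correlated with recurrence is selected from
`W`, its features are screened (z-score rule on `H` rows, Mann–Whitney
tests, Pearson/Spearman cross-correlations, per-feature ROC/AUC with DeLong
intervals), its genes are tested for hypergeometric gene-set enrichment
against a user-supplied GMT with Benjamini–Hochberg correction, and the
**overlap ratio** `O = m/n` measures how many enriched pathways reappear
among the module's own selected pathway-score features.

## Worked example

```
python examples/simulate_and_factorize.py
```

generates a 100-patient cohort with four planted components (gene/pathway
modules of 10 features each, Gaussian noise σ = 0.1), builds the SNF prior
and fits the constrained model (`K = 4, α = β = 0.01`). It prints:

```
iterations run:          500
final relative error:    0.804
final objective:         505.21
mean sample correlation, image    block: 0.853 (95% CI 0.837-0.867)
mean sample correlation, gene     block: 0.739 (95% CI 0.717-0.757)
mean sample correlation, pathway  block: 0.814 (95% CI 0.800-0.827)
```

The relative error is the scale-free residual summed over blocks; the
correlations compare each patient's observed and reconstructed feature
vectors (values near 1 mean `W` captures nearly all structured variation).
`examples/snf_prior.py` walks through the fusion pipeline (spectral ARI =
1.000 on a separable cohort) and `examples/comodule_analysis.py` recovers
the planted recurrence module end to end (overlap ratio O = 1.00, best
biomarker AUC = 1.000).

The same steps are available as a command-line tool:

```
jsnmf simulate --out cohort --seed 7 --n 100
jsnmf pipeline cohort/block1.tsv cohort/block2.tsv cohort/block3.tsv \
      --clinical cohort/clinical.tsv --gmt cohort/genesets.gmt \
      --out run --seed 7
jsnmf grid cohort/block*.tsv --clinical cohort/clinical.tsv --out grid
```

`pipeline` writes `W.tsv`, `H1..3.tsv`, the per-iteration trace, the prior
`R.tsv`, reconstruction metrics, a per-module report and a manifest with
input digests; `grid` sweeps `K ∈ {5,10,15,20}` × `α, β ∈ {0.01,0.1,1,10}`
and flags the relative-error argmin.

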