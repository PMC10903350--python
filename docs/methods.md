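# Methods

## Problem setting

`moscminer` classifies cell subtypes from jointly profiled single-cell
omics layers — gene expression counts, per-CpG DNA methylation (beta
values in [0, 1], frequently missing), and chromatin-accessibility peak
counts — given a table of training labels. The central assumptions are
(i) that the three layers can be put on a common footing by anchoring every
feature to a gene, and (ii) that a per-omics self-attention transform can
both compress each layer to a fixed-size representation and expose which
features the classifier relies on.

## Gene anchoring

All coordinates are handled internally as 0-based half-open; GTF's 1-based
inclusive convention is converted at the parser boundary only, so CpG and
peak interval logic share one convention.

- **Expression.** Genes with zero counts in every cell are removed. Counts
  are scaled per cell to a common target (the median library size unless a
  fixed target is configured) and log(1+x)-transformed; both steps run
  through scanpy.
- **Methylation.** The promoter window of a gene is TSS ± `window_half`
  (default 2,000 bp), half-open on the right and strand-aware (TSS is the
  body start on `+`, body end on `-`). Every CpG inside the window joins
  the gene's CpG cluster; a CpG may serve several genes when windows
  overlap, and genes with no in-window CpG yield no cluster. A cell's
  cluster value is the mean beta over its *observed* member sites. Cells
  with no observed member are imputed with the cluster's mean over cells
  where it is observed; clusters observed nowhere are dropped. The output
  has no missing entries and stays inside [0, 1].
- **Accessibility.** A gene's activity is the sum of peak values over all
  peaks overlapping its gene body by at least 1 bp. Any-overlap (rather
  than containment) is used because peaks straddling a boundary still carry
  signal. Genes overlapped by no peak are dropped.

Feature selection then keeps a feature only if its anchor gene carries a
feature in every omics layer, and min–max normalization rescales each
expression and accessibility feature to [0, 1] — methylation betas already
live there. Inside cross-validation the min/max statistics are fitted on
training cells only and held-out values are clipped to [0, 1]
(`minmax_fit: train_only`); a `whole-dataset` mode exists for parity with
pipelines that normalize before splitting.

## The attention classifier

Per omics with k features, feature j of cell i enters as

    x̂ᵢ⁽ʲ⁾ = e_j xᵢ⁽ʲ⁾                      (embedding, e_j ∈ R^m)
    x̄ᵢ⁽ʲ⁾ = tanh(W₁ x̂ᵢ⁽ʲ⁾ + b₁)            (encoding, R^d)
    sᵢ⁽ʲ⁾ = W₃ tanh(W₂ x̂ᵢ⁽ʲ⁾ + b₂)          (score, W₂ ∈ R^{d_a×m})
    αᵢ    = softmax(sᵢ),  cᵢ = Σ_j αᵢ⁽ʲ⁾ x̄ᵢ⁽ʲ⁾

One context vector cᵢ per omics per cell; context vectors are concatenated
in a fixed omics order (expression, methylation, accessibility — recorded
in the model file) and passed through fc1 → ReLU → dropout → fc2 → softmax.
Training minimizes mean cross-entropy with Adam.

Defaults: m = 128, d = 64, 100 hidden nodes, dropout 0.2, learning rate
1e-3, 300 epochs, batch size 128. Choices the architecture leaves open are
config flags with these defaults:

- `attn_dim` (d_a, the score-layer width): d_a = d = 64;
- hidden activation: ReLU (tanh available);
- embeddings e_j: randomly initialized **and trainable**
  (`train_embeddings=False` freezes them) — frozen random embeddings would
  force all per-feature adaptation through the shared projections;
- dropout is applied after the fc1 activation only.

The per-feature attention weights α are extracted with dropout off and
averaged over cells; the top-k features per omics (default 30) are the
marker candidates. Cross-omics overlap is computed on anchor genes. Each
candidate's normalized abundance is tested with a one-way ANOVA across
subtypes (classic between/within mean squares, p from the F distribution);
raw p < 0.01 flags a candidate as significant. No multiple-testing
correction is applied by default — a Benjamini–Hochberg option exists.

### Implementation and numerics

The network is pure NumPy (float32) with hand-derived gradients. The
embedding is a scaling of e_j, so W₁x̂ = x·(W₁e_j): the projections E·W₁ᵀ
and E·W₂ᵀ are computed once per optimization step and the heavy per-feature
tensors reduce to broadcasts, making CPU training take seconds at fixture
scale. The softmax subtracts the row maximum; cross-entropy floors
probabilities at 1e-12; prediction ties resolve to the lowest class index.
Identical seed + config reproduce models bitwise (one generator drives
initialization, batch shuffling and dropout). The forward pass is verified
against an independent per-feature loop implementation in both the test
suite and the acceptance script.

The scoring head W₃ is initialized at one tenth of its Glorot scale. With a
full-scale initialization the per-sample attention starts far from uniform
and the softmax's rich-get-richer dynamics lock onto features favored by
initialization noise; starting near-uniform lets attention mass accumulate
where gradients actually push it, which is what makes the averaged
attention a usable importance measure.

### No-attention ablation

`build_no_attention_variant` feeds the concatenated normalized features
directly into the same two-layer head (fc1 input width = total feature
count), trained with identical optimizer settings, isolating the
contribution of the attention transform.

## Evaluation

Stratified k-fold cross-validation (default k = 5; stratified because real
subtypes can have only a dozen cells). Metrics: accuracy; support-weighted
F1; the Gorodkin multiclass MCC; and one-vs-rest AUC macro-averaged over
classes, with classes absent from a fold's truth excluded from the mean.
Metrics are computed through scikit-learn and cross-checked in the tests
against a from-scratch implementation (confusion-matrix F1/MCC, rank-based
AUC). Grid search uses a single stratified 80/20 split and picks the
configuration with the best test accuracy (ties → first in grid order).
Baseline classifiers (RF, SVM, logistic regression, naive Bayes) are
exposed as a thin scikit-learn adapter over the same concatenated feature
matrices; they are deliberately not re-implemented.

## Synthetic data

The generator emulates the statistical shape of joint-profiling
experiments so the whole pipeline is testable against known truth:

- **Annotation:** non-overlapping 10 kb gene bodies, 30 kb start-to-start,
  alternating strands on one synthetic chromosome (promoter windows never
  overlap between genes).
- **Expression:** negative-binomial counts (gamma–Poisson, variance
  μ + φμ², φ = 0.5 by default), per-gene base means uniform on [5, 40].
- **Methylation:** per-gene `cpgs_per_promoter` (12) CpG sites placed in
  the promoter window; site betas drawn from a Beta with concentration
  κ = 1 around the gene's cluster mean — strongly bimodal, reflecting
  near-binary single-cell CpG calls — with each site–cell value unobserved
  with probability `meth_missing_rate` (0.3).
- **Accessibility:** `peaks_per_gene` (3) 200 bp peaks inside each gene
  body with Poisson counts, base rates uniform on [1, 4] — sparse and
  non-negative.

Subtype labels are multinomial (uniform by default). Each omics receives
`markers_per_omics` planted marker genes, disjoint across omics by default
so that integrating layers is provably better than any single one; marker
j targets subtype j mod S. `effect_size` is defined uniformly as the
planted mean shift in units of the within-class SD of the **derived
gene-level feature** — the log-scale shift for expression, the
cluster-mean shift (site SD divided by √(expected observed sites)) for
methylation with the direction chosen away from the nearer [0, 1]
boundary, and the per-peak rate shift scaled so the gene-body sum moves by
the stated amount. Defining the effect at the raw site/count level instead
would make the realized effect depend on nuisance parameters
(log-compression, sites per cluster, missingness), so "effect 3" would not
mean the same thing across omics.

`easy_fixture(seed)` is the canonical test condition: 600 cells, 120
genes, 4 subtypes, 10 disjoint markers per omics at effect size 3, fully
preprocessed. It is linearly separable by construction (a multinomial
logistic model fit on half the cells scores ≥ 0.95 held out — asserted in
the tests).

What the generator does **not** emulate: doublets, batch effects,
co-accessibility structure, trans-chromosomal effects, realistic library
size variation, or correlations between omics layers beyond the shared
labels. Passing tests therefore demonstrate correctness of the machinery
and recoverability of planted signal, not performance on real tissue
atlases.

## Problem sizes used in tests and the acceptance script

Fixture-scale runs use a reduced model configuration
(`AttentionConfig.synthetic_scale`: embedding 64, encoded 16, score width
16, 64 hidden nodes, 80 epochs, batch 128) — at 120 features per omics the
full 128-dimensional, 300-epoch configuration is oversized for the
fixture, and the smaller model both trains in ~5 s and yields a cleaner
attention ranking (fewer parameters competing to memorize an already
separable task). Paper-scale defaults remain the package defaults.
Acceptance recomputations: marker recovery over 5 fixture seeds; 5-fold CV
for all 7 omics subsets plus the no-attention variant; 20 random tiny
instances for the equation oracle; 2 repeated runs for determinism.

## Known limitations

- Mean attention is a global importance measure; subtype-specific markers
  are diluted by cells of other subtypes, and strongly redundant markers
  can still share attention unevenly.
- The ANOVA screen assumes approximately normal within-group abundances;
  on min–max-scaled features this is adequate for screening, not for
  calibrated inference (no multiplicity correction by default).
- Min–max statistics are sensitive to single outlier cells; no robust
  scaling option is provided.
- Bitwise determinism holds for the NumPy kernels used here; BLAS-level
  nondeterminism is not expected at these sizes but is not formally
  guaranteed across platforms.
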