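# moscminer

Cell subtype classification from single-cell multi-omics data with an
omics-level self-attention neural network.

Joint single-cell protocols (scChaRM-seq, scNOMeRe-seq, SHARE-seq, ...)
measure gene expression, DNA methylation and chromatin accessibility in the
same cells. Annotating cell subtypes from these data usually relies on
clustering plus manual marker inspection; `moscminer` instead trains a
supervised classifier that integrates the omics layers through their shared
gene anchors and, as a by-product, ranks features by learned importance —
candidate subtype markers.

## Method

Each omics layer is first reduced to a gene-anchored matrix:

- **expression** — genes with no counts anywhere are dropped, counts are
  library-size normalized to the median library and log(1+x)-transformed;
- **methylation** — CpG sites within 2 kb of a gene's TSS form that gene's
  *CpG cluster*; a cell's feature value is the mean beta over its observed
  member sites, mean-imputed when a cell observes none, and clusters
  observed in no cell are dropped;
- **accessibility** — peak signal overlapping the gene body is summed into
  a per-gene activity score.

Features whose anchor gene is missing from any omics are filtered out, and
expression/accessibility are min–max scaled per feature to [0, 1] to match
the methylation betas.

The classifier applies self-attention per omics. With k features and an
m-dimensional embedding e_j per feature j,

    x̂⁽ʲ⁾ = e_j x⁽ʲ⁾
    x̄⁽ʲ⁾ = tanh(W₁ x̂⁽ʲ⁾ + b₁)
    s⁽ʲ⁾  = W₃ tanh(W₂ x̂⁽ʲ⁾ + b₂)
    α     = softmax(s),   c = Σ_j α⁽ʲ⁾ x̄⁽ʲ⁾

so each omics collapses to one attention-pooled context vector c per cell.
Context vectors are concatenated across omics and passed through two fully
connected layers with a softmax head; training minimizes cross-entropy with
Adam (defaults: embedding 128, encoded 64, 100 hidden nodes, dropout 0.2,
lr 1e-3, 300 epochs, batch 128). The per-feature attention weights α,
averaged over cells, rank features as marker candidates; a one-way ANOVA on
the normalized abundances checks that top candidates actually differ
between subtypes (p < 0.01).

The model is implemented in NumPy with hand-derived gradients; because the
embedding is a scaling of e_j, the projections E·W₁ᵀ and E·W₂ᵀ are formed
once per optimization step, which makes CPU training fast. Evaluation uses
stratified 5-fold cross-validation with accuracy, weighted F1, multiclass
(Gorodkin) MCC and macro one-vs-rest AUC.

Since the joint-profiling studies this addresses are not redistributable,
the package ships a synthetic-data generator (`moscminer.synthetic_data`)
producing negative-binomial counts, bimodal beta methylation with
missingness, and sparse peak counts, with known subtype structure and
planted marker genes — every claim the test suite makes is measured against
that known truth.

## Worked example

```python
import moscminer as mm
from moscminer.evaluation import run_cv
from moscminer.markers import marker_report

# 600 cells, 4 subtypes, 120 genes, 10 planted markers per omics (effect 3 SD)
dataset, truth = mm.easy_fixture(seed=1)
config = mm.AttentionConfig.synthetic_scale(seed=1)

result = run_cv(dataset, config, k=5, seed=1)
print("5-fold CV:", {k: round(v, 3) for k, v in result.mean.items()})

model = mm.train(dataset, config)
table, anova = marker_report(dataset, model, top_k=30)
for kind in dataset.omics_kinds:
    planted = set(truth["genes"][kind])
    top = set(table.tables[kind]["anchor_gene"])
    print(f"{kind}: {len(planted & top)}/10 planted markers in top-30, "
          f"{int((anova[anova.omics == kind].p_value < 0.01).sum())}/30 significant at p<0.01")
```

prints

```
5-fold CV: {'accuracy': 1.0, 'f1_weighted': 1.0, 'mcc': 1.0, 'auc': 1.0}
expression: 9/10 planted markers in top-30, 9/30 significant at p<0.01
methylation: 10/10 planted markers in top-30, 10/30 significant at p<0.01
accessibility: 9/10 planted markers in top-30, 9/30 significant at p<0.01
```

The fixture is fully separable, so cross-validated metrics saturate; the
attention ranking recovers nearly all planted markers, and every recovered
marker passes the ANOVA screen (the remaining top-30 entries are noise
features, which correctly fail it).

The same pipeline is available from the shell:

```sh
moscminer simulate --seed 1 --out-dir raw/
moscminer preprocess --expression raw/expression_counts.tsv \
    --methylation raw/methylation_sites.tsv \
    --accessibility raw/accessibility_peaks.tsv \
    --annotation raw/annotation.bed --labels raw/labels.tsv --out-dir pre/
moscminer select --data-dir pre/ --out-dir sel/
moscminer cv --data-dir sel/ --seed 1 --out-dir cv/
moscminer train --data-dir sel/ --seed 1 --out-dir model/
moscminer markers --data-dir sel/ --model model/model.npz --out-dir markers/
```

Every command writes a `manifest.json` (config, seed, input hashes) so runs
reproduce bit for bit.

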