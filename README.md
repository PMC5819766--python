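# sentinelpanel

Design and evaluation of **sentinel gene panels** for targeted
high-throughput transcriptomics: select a fixed-size subset of genes that
(1) represents the diversity of transcriptional responses across a large
corpus of experiments, (2) can serve as a proxy for co-expressed,
unmeasured genes, and (3) covers every pathway of a curated gene-set
collection — then build a linear operator that extrapolates the rest of
the transcriptome from the panel alone.

The intended users are bioinformaticians designing targeted expression
platforms (the L1000-style "measure few, infer many" setting) and anyone
evaluating how well such a panel reconstructs genome-wide fold changes
and pathway-level signals.

## Method

All computation runs on a log2 fold-change matrix **X** (genes ×
comparisons), where each comparison is one treatment-vs-control contrast
and carries a study label.

**Diversity importance (DIS).** Experiments are clustered by k-means
(default k = 10) on the leading *G* eigengenes of X — *G* chosen so the
retained principal components explain 90 % of total variance. Within
each cluster c the components are recomputed and each gene g receives

&nbsp;&nbsp;&nbsp;&nbsp;DIS_c(g) = Σ_{j=1..G} u_{gj}² ,

the summed squared loadings on the leading components. Per-cluster
scores are averaged with the Tukey biweight (robust to outlying
clusters).

**Co-expression importance (CIS).** Studies are partitioned into 20
folds. Within a fold, genes are hierarchically clustered (average
linkage) under the distance 1 − |r| (absolute Pearson correlation) with
the tree cut at h = 0.9; a gene's fold score is its mean squared
correlation with its cluster mates (0 for singletons). Fold scores are
again combined with the Tukey biweight.

**Overall importance (OIS).** With both score vectors ranked ascending
(1 … N),

&nbsp;&nbsp;&nbsp;&nbsp;OIS(g) = √(( rank_CIS(g)² + rank_DIS(g)² ) / 2) / N ∈ (0, 1].

The top-n genes (default n = 1500) form the initial data-driven panel.

**Pathway-coverage refinement.** The panel is iteratively repaired until
every pathway of a GMT collection contains at least q selected genes
(default q = 3, capped at the pathway's attainable size): each iteration
swaps out the selected gene with the fewest pathway memberships and
smallest OIS for the unselected gene belonging to the most uncovered
pathways. Nominated gene lists can then be merged in with provenance
tracking.

**Extrapolation.** Principal component regression: the sentinel
submatrix is decomposed into eigengenes, components are kept while their
variance is within λ (default 0.01) of the leading one, each non-sentinel
gene is regressed on the retained component coordinates, and the
composed t × s operator maps measured sentinel fold changes directly to
predicted non-sentinel fold changes.

**Evaluation.** Pooled Pearson correlation, concordance of the
changed/unchanged call at |log2FC| ≥ 1, overlap of the top-1 %-by-
magnitude entries, and MSE — at the gene level on fold changes and at
the pathway level on fold-change-ranked enrichment scores (weighted
Kolmogorov–Smirnov running sum, ES ∈ [−1, 1]) with differential-pathway
calls at |ES| > 0.5 and KS p < 0.001. A study-level k-fold
cross-validation harness ties it together.

A synthetic-data module generates fold-change corpora with planted
co-expression modules, study structure and module-aligned pathway
collections, so the whole pipeline is testable with known ground truth.

## Worked example

```python
from sentinelpanel import (
    SyntheticSpec, generate_foldchange_corpus, generate_pathways,
    compute_scores, select_top_n, refine_selection,
    fit_extrapolation, evaluate_extrapolation, partition_studies,
)

spec = SyntheticSpec(n_genes=400, n_comparisons=120, n_studies=24,
                     n_modules=5, module_sizes=[30] * 5, latent_rank=5,
                     noise_sd=0.2, n_pathways=40, seed=7)
fcm, truth = generate_foldchange_corpus(spec)
pathways = generate_pathways(truth, spec)

folds = partition_studies(fcm.study_ids, n_folds=4, seed=7)
train = fcm.subset_comparisons(list(folds.index[folds != 0]))
test = fcm.subset_comparisons(list(folds.index[folds == 0]))

scores = compute_scores(train, k=5, n_folds=6, seed=7)
panel = select_top_n(scores, n=60)
refined = refine_selection(panel, pathways, q=3, scores=scores)
print(f"panel size: {len(refined.selection)}  swaps: {len(refined.swaps)}  "
      f"uncovered pathways: {len(refined.residual_uncovered)}")

model = fit_extrapolation(train, refined.selection.genes, lam=0.01)
print(f"retained components K = {model.K}")

gene_ms, path_ms, recall, precision = evaluate_extrapolation(
    model, test, pathways)
print(f"gene level    r={gene_ms.pearson:.2f}  conc={gene_ms.concordance:.2f}  "
      f"overlap={gene_ms.significance_overlap:.2f}  mse={gene_ms.mse:.3f}")
print(f"pathway level r={path_ms.pearson:.2f}  conc={path_ms.concordance:.2f}  "
      f"overlap={path_ms.significance_overlap:.2f}  mse={path_ms.mse:.3f}")
print(f"differential pathways: recall={recall:.2f} precision={precision:.2f}")
```

Output:

```
panel size: 60  swaps: 14  uncovered pathways: 0
retained components K = 5
gene level    r=0.95  conc=0.98  overlap=0.88  mse=0.045
pathway level r=0.84  conc=0.86  overlap=0.75  mse=0.080
differential pathways: recall=0.94 precision=0.75
```

Reading: 14 coverage swaps were needed before all 40 pathways held ≥ 3
panel genes; the extrapolation operator kept the 5 latent components;
held-out fold changes of the 340 non-sentinel genes correlate at r = 0.95
with the measured values, and 94 % of the truly differential pathway
calls are recovered from the sentinel + extrapolated profiles.

The same workflow is available from the shell:

```sh
sentinel-panel simulate --spec spec.yaml --seed 7 --out-prefix sim/
sentinel-panel score    --fold-changes sim/fcm.tsv --studies sim/studies.tsv --out scores.tsv
sentinel-panel select   --scores scores.tsv --gmt sim/pathways.gmt --n 60 --q 3 \
                        --out panel.txt --report coverage.tsv
sentinel-panel fit-extrapolate --fold-changes sim/fcm.tsv --panel panel.txt --out model.h5
sentinel-panel extrapolate     --model model.h5 --sentinel-fc measured.tsv --out predicted.tsv
sentinel-panel crossval --fold-changes sim/fcm.tsv --studies sim/studies.tsv \
                        --gmt sim/pathways.gmt --out report.tsv
```

All outputs carry provenance headers (tool version, config hash, seed);
runs with the same seed are byte-identical.

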