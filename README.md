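# cmvmc — consensus multi-view multi-objective clustering for gene selection

`cmvmc` selects a small, non-redundant set of genes from an expression
matrix by clustering the genes simultaneously under two *views* of
gene–gene similarity and keeping one representative (medoid) gene per
final cluster. It is aimed at transcriptomics workflows (bulk or
single-cell) where thousands of correlated features must be reduced to a
handful of informative genes before downstream sample clustering or
classification — without using sample labels.

## The method

Two symmetric *n* × *n* similarity views over the same genes:

- **View 1 (expression):** `S¹ᵢⱼ = 1 − Eucli(gᵢ, gⱼ)`, the pairwise
  Euclidean distance between expression profiles, scaled by the maximum
  observed distance so the similarity lies in [0, 1].
- **View 2 (function):** `S²ᵢⱼ = (GO-sim(gᵢ, gⱼ) + PPI-sim(gᵢ, gⱼ)) / 2`,
  averaging a Gene Ontology term-set similarity with a protein-interaction
  association score. Both components are pluggable callables; a precomputed
  matrix can be supplied instead.

A candidate state (*parent solution*) encodes one medoid string per view —
an ordered list of 2 … ⌊√n⌋ gene indices; every other gene joins its
most-similar medoid. The two view partitions are merged into a *consensus*
partition by matching maximally overlapping cluster pairs and re-centering
each matched core on its most central common gene. Each state is scored by
three objectives, optimized jointly:

- `XB₁`, `XB₂` — the Xie–Beni index of each view partition (minimized):
  total within-cluster squared dissimilarity over *n* times the squared
  minimum medoid separation, with dissimilarity `d = 1 − S`;
- `AI = (AG + 1) / (DG + 1)` — the Agreement Index between the two view
  partitions (maximized), where `AG` counts positions on which the two
  n × n co-membership matrices agree and `DG = n² − AG`.

Archived Multi-Objective Simulated Annealing (AMOSA) explores the state
space with three moves (replace / add / delete a medoid, applied to both
strings) and maintains a bounded archive of mutually non-dominated
solutions. The archived consensus partitions are then ensembled by
pairwise majority voting — gene pairs co-clustered in a strict majority of
archive members stay together — and the per-cluster medoids of the
ensembled partition are the selected genes. A reduced expression matrix
containing only those rows is written for downstream use, and the same
annealing engine can cluster the samples of the reduced matrix (Xie–Beni
minimized against silhouette maximized) to quantify how well the selection
separates sample classes.

## Worked example

Simulate a two-view data set with four planted co-expressed gene clusters
(120 genes × 20 samples, 30 % irrelevant background genes), then run the
whole pipeline:

```sh
cmvmc simulate --n 120 --d 20 --k 4 --sigma 0.1 --rho 0.9 \
      --noise-frac 0.3 --seed 2 --out-dir sim/
cmvmc pipeline --expression sim/expression.tsv --view2 sim/view2.tsv \
      --labels sim/labels.tsv --seed 2 --out-dir run/
cat run/report.json
```

```json
{
  "n_genes_in": 120,
  "n_genes_selected": 5,
  "ensemble_K": 5,
  "sample_K": 4,
  "sample_silhouette": 0.7003043055906243,
  "classification_accuracy": 100.0
}
```

The ensemble found five clusters — the four planted co-expressed clusters
plus the background block, each recovered exactly — and kept one medoid
gene per cluster (`run/genes.txt`). Clustering the 20 samples on the five
selected genes alone recovers the four planted sample classes exactly
(classification accuracy 100 %) with a mean silhouette of 0.70, versus
about 0.60 on the full 120-gene matrix: the selection sharpens the sample
structure while discarding 96 % of the features.

To build view 2 from annotation data instead of a precomputed matrix:

```sh
cmvmc views --expression X.tsv --gaf annotations.gaf --obo go-basic.obo \
      --ppin interactions.tsv --out-view1 v1.tsv --out-view2 v2.tsv
```

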