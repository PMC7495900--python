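# Methods

This note documents the model behind `cmvmc`, the choices made where the
design was genuinely open, and what the synthetic benchmark does and does
not demonstrate.

## Problem setting

Given an expression matrix `G[n][d]` (*n* genes, *d* samples) and,
optionally, functional annotation data (GO terms per gene, a protein
interaction network), the task is unsupervised gene selection: find a
partition of the genes into K clusters that is simultaneously supported by
expression similarity and functional similarity, and keep one medoid gene
per cluster as the selected, non-redundant feature set. K is not fixed in
advance; the encoding lets it vary in [2, ⌊√n⌋].

## Views

**View 1** is `1 − Eucli(gᵢ, gⱼ)`. As printed, this quantity is negative
whenever a pairwise distance exceeds 1, so by default all pairwise
distances are divided by the maximum observed pairwise distance first;
similarities then lie in [0, 1] with at least one pair at 0. The
unnormalized variant (`normalize="none"`) is kept for audit and returns
the literal arithmetic without range guarantees. The Xie–Beni index is
scale-invariant (a global factor on dissimilarities cancels between
numerator and denominator), so this normalization changes no optimization
outcome; it only fixes the similarity contract. An all-constant matrix has
maximum distance 0; we define all similarities as 1 and warn.

**View 2** averages a GO-based and a PPIN-based pairwise score, both in
[0, 1]. The exact published components of the fused functional measure are
defined outside this package, so both are *pluggable callables*. The
shipped defaults are honest stand-ins with the same contract:

- GO: best-match-average over term pairs of the Jaccard similarity between
  ancestor closures (term + all is_a/part_of ancestors). Identical term
  sets score 1; disjoint ancestries score 0.
- PPIN: the interaction confidence for adjacent proteins, otherwise the
  Jaccard index of their neighbor sets (0 when disconnected with no shared
  neighbors).

Genes without GO annotation cannot be scored in view 2; both views are
restricted to the sorted intersection of their gene sets (`align_views`)
before clustering, mirroring the usual loss of unannotated genes when a
functional view is added.

## Clustering state and objectives

A parent solution holds two independent medoid strings (one per view) and
their consensus. Assignment is nearest-medoid by similarity with ties
broken toward the earliest medoid in the string, so every state decodes
deterministically.

Objectives per state, optimized jointly by AMOSA:

- `XB_v = Σ_k Σ_{x∈C_k} d(x, m_k)² / (n · min_{k≠l} d(m_k, m_l)²)` on
  `d = 1 − S_v` for each view (minimized). Coincident medoids (zero
  separation) score +∞, which removes degenerate states by domination.
- `AI = (AG + 1)/(DG + 1)` between the two view partitions (maximized),
  with co-membership agreement counted over all n² ordered pairs including
  the diagonal. The +1 terms guard the division; the maximum, reached
  exactly when the co-membership relations coincide, is n² + 1.

The agreement-matrix entries are not defined beyond "agreement" in the
source description; the standard co-membership indicator (1 iff the two
genes share a cluster, unit diagonal) is the only convention under which
AG + DG = n² holds, and it is what `cmvmc` uses.

## Consensus construction

1. Build the K₁ × K₂ contingency table of the two view partitions.
2. Match cluster pairs greedily by descending overlap (ties to the
   lexicographically lowest index pair), each cluster used at most once,
   stopping when remaining overlaps are zero. Greedy matching (rather than
   optimal assignment) is deliberate: it is deterministic, cheap, and
   matches the "maximum overlapping clusters" description.
3. Each matched pair's common genes form a core; its medoid is the common
   gene with the highest mean combined similarity (S¹+S²)/2 to the other
   common genes (a singleton core is its own medoid; ties to the lowest
   gene index).
4. Every remaining gene joins the core with the highest mean combined
   similarity over the core's (fixed) members.
5. If fewer than two matched cores exist, the view partition with the
   lower Xie–Beni index is copied as the consensus — the degenerate case
   is not covered by the source description, and this fallback keeps every
   state evaluable.

## AMOSA

The annealer keeps a bounded archive of mutually non-dominated solutions
(soft limit 40, pruned to 20 by single-linkage clustering of objective
vectors, keeping the member nearest its cluster centroid; exact-count tree
cuts are used so tied merge heights cannot collapse the archive). Moves
dominated on average by `Δdom` are accepted with probability
`1/(1 + exp(Δdom/T))`; `Δdom` is a product over differing objectives of
range-normalized gaps, with ranges tracked online over the run. The full
case analysis on (current point, new point, archive) is implemented,
including the re-seat to the least-dominating archive member when the new
point dominates the current one but is itself dominated.

Cooling is geometric: Tmax = 100, Tmin = 1e−4, α = 0.9, 50 moves per
level (≈ 6 500 evaluations per run). These magnitudes are conventional for
archived annealing; the source description fixes none of them, and all are
exposed in the `amosa:` config section. One seeded generator drives the
whole run; identical seeds give bit-identical archives.

Perturbations draw one of three operators uniformly — replace a random
medoid with a random non-medoid gene, add a random non-medoid gene, or
delete a random medoid. An operator that would push an affected string's K
outside [2, ⌊√n⌋] is re-drawn, so replace is always available and K never
leaves its bounds. Whether a move should touch one view string or both at
once is genuinely open; `cmvmc` perturbs **one string per move** (chosen
uniformly), with the both-strings variant available as an option. The
reason is search dynamics: coupled moves cannot improve one view's string
without simultaneously randomizing the other's, so joint optima are
reachable only through lucky simultaneous draws. On the planted benchmark
the coupled variant leaves the annealer stuck on partial fronts in about a
third of noiseless runs (where the expression view degenerates to an exact
0/1 block matrix and the joint optimum must be assembled view by view),
while the one-string-per-move walk recovers the planted partition in 19/20
noiseless and 10/10 noisy runs.

## Ensemble and selection

All archived consensus partitions vote, unweighted. Gene pairs
co-clustered in strictly more than half of them are connected; connected
components of size ≥ 2 are core clusters; leftovers join the core with the
highest mean combined similarity. If fewer than two cores emerge (total
disagreement), the archived partition with the lowest mean Xie–Beni across
the two views is returned. Selected genes are the per-cluster medoids of
the ensembled partition, so the number of selected genes equals the final
K and the selected genes are pairwise in different clusters.

## Downstream sample clustering

To score a selection, the d samples of the (reduced) matrix are clustered
with the same annealing engine on Euclidean dissimilarity between sample
profiles, K ∈ [2, ⌊√d⌋], with objectives (Xie–Beni minimized, mean
silhouette maximized); the reported partition is the archive member with
the best silhouette. The source description ranks selections by
silhouette, which motivates both the second objective and the selection
rule; this is an interpretation, flagged as such. Classification accuracy
maps each sample cluster to its modal class (ties to the class occurring
earliest in the cluster); a Hungarian one-to-one mapping is available
behind a flag.

## Synthetic benchmark

The generator emulates the pipeline's input shape with known truth:

- `n = 120` genes × `d = 20` samples, `K* = 4` planted co-expressed
  clusters, within-cluster Gaussian noise `σ = 0.1` (on the 0–1 prototype
  scale), view-2 concordance `ρ = 0.9`, 30 % noise genes, 4 sample classes.
- Prototypes are one-hot across sample classes (cluster k elevated in
  class k): all between-cluster expression distances are equal, so no
  merge of planted clusters is cheaper than another — the benchmark probes
  K-selection, not a particular merge order. When classes < clusters the
  generator falls back to binary codes, then graded levels.
- Noise genes are Uniform(0, 1) background features with no sample-class
  structure; the planted truth assigns them to a designated extra cluster
  (label K*). View 2 is block-structured over the full planted partition:
  within-block similarities ~ U(0.7, 0.9), between ~ U(0.1, 0.3), after
  which a fraction (1 − ρ) of genes have their rows resampled to random
  levels.

Under these conditions the pipeline typically recovers the complete
planted partition — the four co-expressed clusters one-to-one plus the
background block isolated as its own cluster — giving an adjusted Rand
index of 1.0 against the truth and five selected genes. Two rare residual
failure modes remain: the majority vote can merge the background block
into one signal cluster (the four signal clusters are still recovered
exactly, full-partition ARI ≈ 0.73), and in the fully degenerate noiseless
limit the non-dominated archive can shrink to two partitions whose
unanimity vote over-fragments a cluster. The acceptance suite therefore
requires ARI ≥ 0.9 *and* all four signal clusters recovered in at least
4 of 5 seeded runs, and the acceptance script reports a 5-replicate
summary.

What passing does **not** show: the generator has no batch effects, no
heavy-tailed or count noise, no dropout, and its functional view is a
clean block matrix rather than a real GO/PPIN-derived similarity. Results
on it demonstrate the machinery (encoding, objectives, annealing,
consensus, vote) end to end, not performance on real microarray or
single-cell data.

A deliberately non-physical detail: uniform background genes in a bounded
box are mutually closer than they are to the structured clusters, so they
form a coherent "background module" that the method isolates and
represents with one medoid. Making them mutually incoherent instead
requires widening their range until they become distance outliers, which
creates degenerate one-outlier-medoid states with near-zero Xie–Beni — a
known pathology of the index — and was rejected.

## Numerical conventions

- Dissimilarity is always `1 − S`; similarity matrices are clipped to
  [0, 1], symmetrized, and given a unit diagonal on construction.
- +∞ sentinels (coincident medoids in Xie–Beni and Davies–Bouldin) are
  clamped to finite extremes only inside archive pruning, where a metric
  is needed.
- Silhouette follows the precomputed-dissimilarity definition; singleton
  clusters and points with a = b = 0 contribute 0.
- All randomness flows through one explicitly passed numpy Generator; no
  global state. Runs are bit-reproducible per seed.
- All indices are 0-based; on-disk cluster labels are 0-based integers.

## Known limitations

- Exactly two views; the containers would hold v views but the consensus
  and objective logic are written for v = 2.
- Crisp (non-fuzzy) memberships only.
- The default functional similarities are documented stand-ins, not the
  published fused measure; supply exact callables or a precomputed matrix
  for faithful view-2 scores.
- O(n²) memory in the number of genes (dense similarity matrices); tens of
  thousands of genes need blocking or sparsification that this package
  does not provide.
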