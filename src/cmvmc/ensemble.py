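"""Majority-vote ensembling of archived consensus partitions and gene selection.

The annealing run ends with an archive of non-dominated parent solutions,
each carrying a consensus partition of the genes. The ensemble keeps a pair
of genes together when they are co-clustered in a strict majority of those
partitions; connected components of the resulting co-clustering graph (size
>= 2) become core clusters, and the leftover genes are placed by maximum
average combined similarity, exactly as in the consensus step. The final
selected genes are the per-cluster medoids of the ensembled partition.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np

from .amosa import Archive
from .datamodel import ExpressionMatrix, Partition, SimilarityView
from .mvclust import MedoidString, ParentSolution, _central_gene, _combined, xb_index


def _best_xb_fallback(
    partitions: Sequence[Partition],
    view1: SimilarityView,
    view2: SimilarityView,
) -> Partition:
    """Partition with the lowest mean Xie-Beni across the two views."""
    best, best_score = None, np.inf
    for p in partitions:
        meds = extract_medoid_indices(p, view1, view2)
        ms = MedoidString(tuple(meds))
        score = np.mean([xb_index(p, ms, view1), xb_index(p, ms, view2)])
        if score < best_score:
            best, best_score = p, float(score)
    assert best is not None
    return Partition(labels=best.labels.copy(), K=best.K)


def majority_vote(
    partitions: Sequence[Partition],
    view1: SimilarityView,
    view2: SimilarityView,
    threshold: float = 0.5,
) -> Partition:
    """Ensemble partitions by pairwise majority voting.

    Gene pairs co-clustered in more than ``threshold`` (default strict
    majority) of the input partitions are connected; connected components
    with at least two genes are the core clusters, labeled in order of
    their lowest gene index. Genes outside every core join the core with
    the highest mean combined similarity. If fewer than two cores emerge,
    the input partition with the best mean Xie-Beni over the two views is
    returned instead.
    """
    if not partitions:
        raise ValueError("need at least one partition to ensemble")
    n = partitions[0].n
    if any(p.n != n for p in partitions):
        raise ValueError("partitions cover different numbers of genes")
    if n != view1.n or n != view2.n:
        raise ValueError("views do not match the partitions' gene count")
    votes = np.zeros((n, n), dtype=int)
    for p in partitions:
        votes += p.comembership()
    keep = votes > threshold * len(partitions)
    np.fill_diagonal(keep, False)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(*np.nonzero(np.triu(keep))))
    cores = sorted(
        (sorted(c) for c in nx.connected_components(g) if len(c) >= 2),
        key=lambda c: c[0],
    )
    if len(cores) < 2:
        return _best_xb_fallback(partitions, view1, view2)
    combined = _combined(view1, view2)
    labels = np.full(n, -1, dtype=int)
    for k, core in enumerate(cores):
        labels[core] = k
    unassigned = np.flatnonzero(labels == -1)
    if len(unassigned):
        scores = np.column_stack(
            [combined[:, core].mean(axis=1) for core in cores]
        )
        labels[unassigned] = np.argmax(scores[unassigned], axis=1)
    return Partition(labels=labels, K=len(cores))


def extract_medoid_indices(
    p: Partition, view1: SimilarityView, view2: SimilarityView
) -> list[int]:
    """Per-cluster gene index maximizing mean combined similarity to co-members."""
    combined = _combined(view1, view2)
    return [_central_gene(p.members(k), combined) for k in range(p.K)]


def extract_medoids(
    p: Partition, view1: SimilarityView, view2: SimilarityView
) -> list[str]:
    """Ordered candidate gene ids: one medoid per cluster of ``p``.

    Singleton clusters contribute their only gene; ties break toward the
    lowest gene index. The output length equals K.
    """
    return [view1.gene_ids[i] for i in extract_medoid_indices(p, view1, view2)]


def select_genes(
    em: ExpressionMatrix,
    archive: Archive,
    view1: SimilarityView,
    view2: SimilarityView,
    threshold: float = 0.5,
) -> tuple[list[str], Partition, ExpressionMatrix]:
    """Full selection stage: ensemble the archive, pick medoids, reduce.

    Returns the candidate gene ids, the ensembled partition, and the
    reduced expression matrix (candidate rows only, original sample order).
    """
    solutions: list[ParentSolution] = archive.solutions()
    partitions = [s.partition3 for s in solutions if s.partition3 is not None]
    if not partitions:
        raise ValueError("archive has no consensus partitions")
    final = majority_vote(partitions, view1, view2, threshold=threshold)
    cand = extract_medoids(final, view1, view2)
    reduced = em.subset_genes(cand)
    assert len(cand) < em.n_genes
    return cand, final, reduced
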