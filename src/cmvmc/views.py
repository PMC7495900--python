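"""Construction of the two gene-gene similarity views.

View 1 is expression-based: similarity is one minus the pairwise Euclidean
distance between gene expression profiles. Because raw Euclidean distances
are unbounded, the default scales all distances by the maximum observed
pairwise distance before subtracting from 1, which keeps similarities in
[0, 1]; ``normalize="none"`` keeps the literal ``1 - Eucli`` arithmetic for
audit (it can go negative and violates the SimilarityView range contract,
so it is returned raw).

View 2 is functional: the average of a GO-based term-set similarity and a
PPIN-based association score for each gene pair. Both components are
pluggable callables with a [0, 1] contract; the shipped defaults are a
best-match-average of Jaccard similarity between ancestor sets of annotated
GO terms, and interaction confidence (falling back to neighborhood Jaccard)
on the protein network.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datamodel import (
    ExpressionMatrix,
    GeneAnnotation,
    OntologyGraph,
    PPINetwork,
    SimilarityView,
)

logger = logging.getLogger("cmvmc")

GoSim = Callable[[str, str], float]
PpiSim = Callable[[str, str], float]


def build_view1(em: ExpressionMatrix, normalize: str = "minmax") -> SimilarityView:
    """Expression view: S[i][j] = 1 - (scaled) Euclidean distance.

    With ``normalize="minmax"`` (default) distances are divided by the
    maximum pairwise distance so the similarity lands in [0, 1]. An
    all-constant matrix (maximum distance 0) yields all similarities 1 with
    a warning.
    """
    if normalize not in ("minmax", "none"):
        raise ValueError("normalize must be 'minmax' or 'none'")
    d = squareform(pdist(em.values, metric="euclidean"))
    if normalize == "minmax":
        dmax = d.max()
        if dmax == 0.0:
            logger.warning("all expression profiles identical; all similarities set to 1")
        else:
            d = d / dmax
    s = 1.0 - d
    np.fill_diagonal(s, 1.0)
    if normalize == "none":
        # literal arithmetic: may leave [0, 1]; hand back the raw matrix
        view = SimilarityView.__new__(SimilarityView)
        view.gene_ids = list(em.gene_ids)
        view.matrix = s
        return view
    return SimilarityView(list(em.gene_ids), s)


# ---------------------------------------------------------------------------
# default pluggable similarity components for view 2
# ---------------------------------------------------------------------------


def default_go_sim(ann: GeneAnnotation, onto: OntologyGraph) -> GoSim:
    """Best-match-average of Jaccard similarity between term ancestor sets.

    For genes ``a`` and ``b`` with annotated term sets ``T_a`` and ``T_b``,
    each term pair is scored by the Jaccard index of their ancestor closures
    (the term plus all is_a / part_of ancestors); the gene-pair score is the
    symmetric best-match average. Identical term sets score 1.
    """
    cache: dict[str, set[str]] = {}

    def anc(term: str) -> set[str]:
        if term not in cache:
            cache[term] = onto.ancestors(term)
        return cache[term]

    def sim(a: str, b: str) -> float:
        ta, tb = ann.terms.get(a), ann.terms.get(b)
        if not ta or not tb:
            raise ValueError(f"gene without annotations: {a if not ta else b!r}")
        if ta == tb:
            return 1.0
        pair = np.empty((len(ta), len(tb)))
        for i, t in enumerate(sorted(ta)):
            for j, u in enumerate(sorted(tb)):
                A, B = anc(t), anc(u)
                inter = len(A & B)
                pair[i, j] = inter / len(A | B) if inter else 0.0
        return float((pair.max(axis=1).mean() + pair.max(axis=0).mean()) / 2.0)

    return sim


def default_ppi_sim(ppin: PPINetwork) -> PpiSim:
    """Interaction confidence for adjacent proteins, else neighborhood Jaccard."""

    def sim(a: str, b: str) -> float:
        pa, pb = ppin.protein(a), ppin.protein(b)
        conf = ppin.confidence(pa, pb)
        if conf is not None:
            return conf
        na, nb = ppin.neighbors(pa), ppin.neighbors(pb)
        union = na | nb
        if not union:
            return 0.0
        return len(na & nb) / len(union)

    return sim


def build_view2(
    ann: GeneAnnotation,
    onto: OntologyGraph,
    ppin: PPINetwork,
    gene_ids: Sequence[str],
    go_sim: GoSim | None = None,
    ppi_sim: PpiSim | None = None,
) -> SimilarityView:
    """Functional view: S[i][j] = (go_sim(i, j) + ppi_sim(i, j)) / 2.

    Every gene in ``gene_ids`` must carry at least one GO annotation; genes
    without annotations must be excluded (via :func:`align_views` /
    ``GeneAnnotation.unmapped``) before calling.
    """
    unannotated = [g for g in gene_ids if not ann.terms.get(g)]
    if unannotated:
        raise ValueError(
            f"gene(s) without annotations must be excluded first: {unannotated[:5]}"
        )
    go_sim = go_sim or default_go_sim(ann, onto)
    ppi_sim = ppi_sim or default_ppi_sim(ppin)
    n = len(gene_ids)
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            g = float(go_sim(gene_ids[i], gene_ids[j]))
            p = float(ppi_sim(gene_ids[i], gene_ids[j]))
            for name, val in (("go_sim", g), ("ppi_sim", p)):
                if not 0.0 <= val <= 1.0:
                    raise ValueError(
                        f"{name}({gene_ids[i]}, {gene_ids[j]}) = {val} outside [0, 1]"
                    )
            s[i, j] = s[j, i] = (g + p) / 2.0
    return SimilarityView(list(gene_ids), s)


def align_views(
    views: Sequence[SimilarityView],
) -> tuple[list[str], list[SimilarityView]]:
    """Re-index every view to the sorted intersection of their gene sets.

    All downstream clustering runs on the aligned output only. Fails if the
    intersection holds fewer than 4 genes (the medoid encoding needs
    ``floor(sqrt(n)) >= 2``).
    """
    if len(views) < 2:
        raise ValueError("align_views needs at least 2 views")
    common = set(views[0].gene_ids)
    for v in views[1:]:
        common &= set(v.gene_ids)
    if not common:
        raise ValueError("views share no genes")
    if len(common) < 4:
        raise ValueError(f"only {len(common)} genes shared between views; need >= 4")
    order = sorted(common)
    return order, [v.restrict(order) for v in views]
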