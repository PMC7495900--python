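"""Shared containers and readers/writers for every format the pipeline touches.

The pipeline works on two in-memory objects almost exclusively: an
:class:`ExpressionMatrix` (genes x samples) and one or more
:class:`SimilarityView` objects (symmetric gene-gene similarity in [0, 1]).
The GO / PPIN containers exist only to feed the functional-similarity view
builder; clustering itself never sees them.

All indices are 0-based throughout the code base, and cluster labels written
to disk are 0-based integers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("cmvmc")

_SIM_TOL = 1e-12
_ASYM_TOL = 1e-8

#: GAF aspect letter for each Gene Ontology namespace.
NAMESPACE_ASPECT = {"BP": "P", "MF": "F", "CC": "C"}
ASPECT_NAMESPACE = {v: k for k, v in NAMESPACE_ASPECT.items()}


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with identifiers and optional class labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, d = self.values.shape
        if len(self.gene_ids) != n or len(self.sample_ids) != d:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.gene_ids)) != n:
            dupes = [g for g in self.gene_ids if self.gene_ids.count(g) > 1]
            raise ValueError(f"duplicate gene id: {dupes[0]!r}")
        if n < 2 or d < 2:
            raise ValueError(f"need at least 2 genes and 2 samples, got {n}x{d}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if self.sample_labels is not None and len(self.sample_labels) != d:
            raise ValueError("sample_labels length does not match sample count")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Reduced matrix keeping only ``gene_ids`` rows, sample order intact."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"unknown gene id in subset: {missing[0]!r}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :].copy(),
            sample_labels=list(self.sample_labels) if self.sample_labels else None,
        )


@dataclass
class SimilarityView:
    """Symmetric n x n gene-gene similarity matrix with entries in [0, 1].

    The diagonal is always 1 (every gene is maximally similar to itself).
    """

    gene_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene ids in similarity view")
        if self.matrix.shape != (n, n):
            raise ValueError("similarity matrix shape does not match gene ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=_ASYM_TOL, rtol=0.0):
            raise ValueError("similarity matrix is not symmetric")
        if (self.matrix < -_SIM_TOL).any() or (self.matrix > 1.0 + _SIM_TOL).any():
            bad = np.argwhere((self.matrix < -_SIM_TOL) | (self.matrix > 1 + _SIM_TOL))[0]
            raise ValueError(
                f"similarity entry out of [0, 1] at "
                f"({self.gene_ids[bad[0]]}, {self.gene_ids[bad[1]]}): "
                f"{self.matrix[bad[0], bad[1]]}"
            )
        # normalize representation: exact symmetry, clipped range, unit diagonal
        self.matrix = np.clip((self.matrix + self.matrix.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.matrix, 1.0)

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def dissimilarity(self) -> np.ndarray:
        """1 - S, the crisp dissimilarity used by the Xie-Beni index."""
        d = 1.0 - self.matrix
        np.fill_diagonal(d, 0.0)
        return d

    def restrict(self, gene_ids: Sequence[str]) -> "SimilarityView":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = np.array([index[g] for g in gene_ids], dtype=int)
        return SimilarityView(list(gene_ids), self.matrix[np.ix_(rows, rows)])


@dataclass
class Partition:
    """Total assignment of n elements to K labeled clusters (labels 0..K-1)."""

    labels: np.ndarray
    K: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        used = np.unique(self.labels)
        k = len(used)
        if not np.array_equal(used, np.arange(k)):
            raise ValueError("cluster labels must be exactly 0..K-1 with all used")
        if k < 1:
            raise ValueError("a partition needs at least 1 cluster")
        if self.K == 0:
            self.K = k
        elif self.K != k:
            raise ValueError(f"declared K={self.K} but {k} labels are used")

    @property
    def n(self) -> int:
        return len(self.labels)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def comembership(self) -> np.ndarray:
        """Binary agreement matrix: entry (i, j) = 1 iff i and j share a cluster."""
        return (self.labels[:, None] == self.labels[None, :]).astype(np.int8)


@dataclass
class GeneAnnotation:
    """gene id -> set of ontology term ids (restricted to loaded, live terms)."""

    terms: dict[str, set[str]]
    unmapped: list[str] = field(default_factory=list)

    def genes(self) -> list[str]:
        return sorted(self.terms)


@dataclass
class OntologyGraph:
    """DAG of ontology terms; edges point child -> parent (is_a / part_of)."""

    graph: nx.MultiDiGraph

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def ancestors(self, term: str) -> set[str]:
        """The term itself plus everything reachable via is_a / part_of."""
        return {term} | nx.descendants(self.graph, term)


@dataclass
class PPINetwork:
    """Undirected protein interaction graph with edge confidences in [0, 1]."""

    graph: nx.Graph
    gene_to_protein: dict[str, str] = field(default_factory=dict)

    def protein(self, gene_id: str) -> str:
        # identity mapping unless an explicit gene -> protein map was given
        return self.gene_to_protein.get(gene_id, gene_id)

    def confidence(self, a: str, b: str) -> float | None:
        if self.graph.has_edge(a, b):
            return float(self.graph[a][b].get("confidence", 1.0))
        return None

    def neighbors(self, protein: str) -> set[str]:
        if protein in self.graph:
            return set(self.graph[protein])
        return set()


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_expression(
    path: str | Path,
    genes_in: str = "rows",
    label_row: str | None = None,
) -> ExpressionMatrix:
    """Load a TSV/CSV expression table with genes on rows or columns.

    Parameters
    ----------
    path:
        Delimited text file with a header line; the first column (or row,
        with ``genes_in="columns"``) holds gene identifiers.
    genes_in:
        ``"rows"`` (default) or ``"columns"`` — on-disk orientation. The
        returned matrix always has genes on rows.
    label_row:
        Optional identifier of a row (in gene orientation) carrying sample
        class labels; it is removed from the matrix and stored as
        ``sample_labels``.

    Rows containing missing or non-numeric cells are dropped with a logged
    count. Duplicate gene identifiers and matrices smaller than 2x2 are
    rejected.
    """
    if genes_in not in ("rows", "columns"):
        raise ValueError("genes_in must be 'rows' or 'columns'")
    df = pd.read_csv(path, sep=_sep_for(Path(path)), index_col=0, dtype=str)
    if genes_in == "columns":
        df = df.T
    labels: list[str] | None = None
    if label_row is not None:
        if label_row not in df.index:
            raise ValueError(f"label row {label_row!r} not found in {path}")
        labels = [str(x) for x in df.loc[label_row]]
        df = df.drop(index=label_row)
    ids = [str(g) for g in df.index]
    seen: set[str] = set()
    for g in ids:
        if g in seen:
            raise ValueError(f"duplicate gene id: {g!r}")
        seen.add(g)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    keep = ~numeric.isna().any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning(
            "dropped %d gene row(s) with missing/non-numeric values: %s",
            dropped,
            ", ".join(str(g) for g in df.index[~keep][:10]),
        )
    numeric = numeric.loc[keep]
    return ExpressionMatrix(
        gene_ids=[str(g) for g in numeric.index],
        sample_ids=[str(s) for s in numeric.columns],
        values=numeric.to_numpy(dtype=float),
        sample_labels=labels,
    )


def read_similarity(path: str | Path) -> SimilarityView:
    """Load a precomputed square similarity matrix (gene ids on both axes).

    Small asymmetries (<= 1e-8) are averaged away; the diagonal is forced to
    1. Entries outside [0, 1] beyond tolerance are rejected with the
    offending cell named.
    """
    df = pd.read_csv(path, sep=_sep_for(Path(path)), index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"similarity matrix in {path} is not square: {df.shape}")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise ValueError(f"row and column gene ids differ in {path}")
    m = df.to_numpy(dtype=float)
    asym = np.abs(m - m.T).max() if m.size else 0.0
    if asym > _ASYM_TOL:
        raise ValueError(f"similarity matrix in {path} is asymmetric (max |M-M'|={asym:g})")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return SimilarityView(rows, m)


def read_partition(path: str | Path) -> tuple[list[str], Partition]:
    """Read a two-column (id, cluster) TSV written by :func:`write_partition`."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: int})
    ids = [str(x) for x in df.iloc[:, 0]]
    return ids, Partition(labels=df.iloc[:, 1].to_numpy(dtype=int))


def read_annotations(
    gaf_path: str | Path,
    obo_path: str | Path,
    namespaces: Iterable[str] = ("BP", "MF", "CC"),
    id_column: str = "symbol",
) -> tuple[GeneAnnotation, OntologyGraph]:
    """Parse a GAF 2.x annotation file against an OBO ontology.

    Annotations are restricted to the requested namespaces ({BP, MF, CC});
    terms absent from the ontology (including obsolete ones, which obonet
    drops at load time) are discarded with a warning. Genes left with zero
    surviving annotations are reported in ``GeneAnnotation.unmapped``.

    ``id_column`` selects the GAF identifier used as gene id: ``"symbol"``
    (column 3, default) or ``"object_id"`` (column 2).
    """
    import obonet

    namespaces = set(namespaces)
    bad_ns = namespaces - set(NAMESPACE_ASPECT)
    if bad_ns:
        raise ValueError(f"unknown namespace(s): {sorted(bad_ns)}")
    aspects = {NAMESPACE_ASPECT[ns] for ns in namespaces}
    graph = obonet.read_obo(str(obo_path))
    onto = OntologyGraph(graph)

    id_idx = {"object_id": 1, "symbol": 2}[id_column]
    terms: dict[str, set[str]] = {}
    seen_genes: set[str] = set()
    missing_terms: set[str] = set()
    with open(gaf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            gene, term, aspect = cols[id_idx], cols[4], cols[8]
            qualifier = cols[3]
            if "NOT" in qualifier.split("|"):
                continue
            seen_genes.add(gene)
            if aspect not in aspects:
                continue
            if term not in graph:
                missing_terms.add(term)
                continue
            terms.setdefault(gene, set()).add(term)
    if missing_terms:
        logger.warning(
            "%d GAF term(s) absent from the ontology (obsolete or unknown), dropped: %s",
            len(missing_terms),
            ", ".join(sorted(missing_terms)[:10]),
        )
    unmapped = sorted(seen_genes - set(terms))
    if unmapped:
        logger.warning("%d gene(s) have no surviving GO annotation: %s",
                       len(unmapped), ", ".join(unmapped[:10]))
    return GeneAnnotation(terms=terms, unmapped=unmapped), onto


def read_ppin(
    path: str | Path,
    dialect: str = "tsv-edges",
    gene_map: Mapping[str, str] | None = None,
) -> PPINetwork:
    """Load a protein-protein interaction network.

    ``tsv-edges``: two id columns plus an optional confidence column.
    ``psi-mitab``: PSI-MITAB 2.5+ — ids from columns 1-2 (``db:accession``),
    confidence parsed from the scores column when it carries a
    ``...score:x`` entry.

    Edges are undirected and deduplicated keeping the maximum confidence;
    self-loops are removed; an unreadable score becomes 1.0 with a warning.
    """
    g = nx.Graph()

    def add_edge(a: str, b: str, conf: float) -> None:
        if a == b:
            return
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
        else:
            g.add_edge(a, b, confidence=conf)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if dialect == "tsv-edges":
                if lineno == 1 and _looks_like_header(cols):
                    continue
                if len(cols) < 2:
                    continue
                a, b = cols[0].strip(), cols[1].strip()
                conf = 1.0
                if len(cols) >= 3 and cols[2].strip():
                    try:
                        conf = float(cols[2])
                    except ValueError:
                        logger.warning("unreadable score %r on line %d; using 1.0",
                                       cols[2], lineno)
                add_edge(a, b, conf)
            elif dialect == "psi-mitab":
                if len(cols) < 2:
                    continue
                a = cols[0].split(":", 1)[-1].strip()
                b = cols[1].split(":", 1)[-1].strip()
                conf = 1.0
                if len(cols) >= 15 and cols[14].strip() not in ("", "-"):
                    score = cols[14].split("|")[0]
                    try:
                        conf = float(score.rsplit(":", 1)[-1])
                    except ValueError:
                        logger.warning("unreadable MITAB score %r on line %d; using 1.0",
                                       cols[14], lineno)
                add_edge(a, b, conf)
            else:
                raise ValueError(f"unknown PPIN dialect: {dialect!r}")
    return PPINetwork(graph=g, gene_to_protein=dict(gene_map or {}))


def _looks_like_header(cols: list[str]) -> bool:
    if len(cols) < 3:
        return False
    try:
        float(cols[2])
        return False
    except ValueError:
        return True


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Two-column (gene id, protein id) TSV used to bridge expression and PPIN ids."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_partition(p: Partition, ids: Sequence[str], path: str | Path) -> None:
    """Write a partition as a two-column (id, cluster) TSV."""
    if len(ids) != p.n:
        raise ValueError("id list length does not match partition size")
    pd.DataFrame({"id": list(ids), "cluster": p.labels}).to_csv(
        path, sep="\t", index=False
    )


def write_gene_list(gene_ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_ids))


def write_reduced(
    em: ExpressionMatrix, gene_ids: Sequence[str], path: str | Path
) -> ExpressionMatrix:
    """Write the reduced expression matrix keeping only ``gene_ids`` rows."""
    reduced = em.subset_genes(gene_ids)
    df = pd.DataFrame(reduced.values, index=reduced.gene_ids, columns=reduced.sample_ids)
    df.to_csv(path, sep=_sep_for(Path(path)), index_label="gene")
    return reduced


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(em.values, index=em.gene_ids, columns=em.sample_ids)
    df.to_csv(path, sep=_sep_for(Path(path)), index_label="gene")


def write_similarity(view: SimilarityView, path: str | Path) -> None:
    df = pd.DataFrame(view.matrix, index=view.gene_ids, columns=view.gene_ids)
    df.to_csv(path, sep=_sep_for(Path(path)), index_label="gene")
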