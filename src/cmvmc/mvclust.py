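"""Multi-view medoid clustering core.

Each candidate state (*parent solution*) encodes three medoid strings: one
per similarity view plus their consensus. A medoid string is an ordered
list of 2..floor(sqrt(n)) distinct gene indices; every other gene joins the
cluster of its most-similar medoid under the string's view. The consensus
string/partition is rebuilt at every evaluation by matching maximally
overlapping cluster pairs between the two view partitions, re-centering
each matched core on its most centrally located common gene, and placing
the remaining genes by maximum average combined similarity.

Objectives per solution: the Xie-Beni index of each view partition
(minimized) and the Agreement Index between the two view partitions
(maximized). The archived multi-objective simulated annealing engine in
:mod:`cmvmc.amosa` drives the search; three perturbation operators
(replace / add / delete a medoid) applied to both view strings move
between states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .amosa import AnnealConfig, Archive, ObjectiveVector, anneal
from .datamodel import Partition, SimilarityView

XB_DIRECTIONS = ("min", "min", "max")


def k_max(n: int) -> int:
    """Upper bound on the encoded cluster count: floor(sqrt(n))."""
    return int(math.isqrt(n))


@dataclass(frozen=True)
class MedoidString:
    """Ordered distinct gene indices serving as cluster representatives."""

    medoids: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.medoids)) != len(self.medoids):
            raise ValueError("duplicate medoid in string")
        if len(self.medoids) < 2:
            raise ValueError("a medoid string needs at least 2 medoids")

    @property
    def K(self) -> int:
        return len(self.medoids)


@dataclass
class ParentSolution:
    """One candidate state: two view strings, their consensus, and objectives."""

    string1: MedoidString
    string2: MedoidString
    string3: MedoidString | None = None  # null until the first evaluation
    partition1: Partition | None = None
    partition2: Partition | None = None
    partition3: Partition | None = None
    objectives: ObjectiveVector | None = None


def init_solution(n: int, rng: np.random.Generator) -> ParentSolution:
    """Random solution: K1, K2 ~ Uniform[2, floor(sqrt(n))], medoids w/o replacement."""
    kmax = k_max(n)
    if kmax < 2:
        raise ValueError(f"need n >= 4 genes (floor(sqrt(n)) >= 2), got n={n}")
    strings = []
    for _ in range(2):
        k = int(rng.integers(2, kmax + 1))
        strings.append(MedoidString(tuple(int(x) for x in
                                          rng.choice(n, size=k, replace=False))))
    return ParentSolution(string1=strings[0], string2=strings[1])


def assign_genes(ms: MedoidString, view: SimilarityView) -> Partition:
    """Each gene joins its most-similar medoid's cluster.

    Cluster k is the cluster of the k-th medoid in the string; ties are
    broken toward the lowest medoid position. Medoids always land in their
    own cluster (self-similarity is 1).
    """
    med = np.asarray(ms.medoids, dtype=int)
    if med.max() >= view.n:
        raise IndexError("medoid index outside the view")
    sims = view.matrix[:, med]                      # n x K
    labels = np.argmax(sims, axis=1)                # first max -> lowest position
    labels[med] = np.arange(ms.K)
    return Partition(labels=labels, K=ms.K)


def _greedy_overlap_matching(p1: Partition, p2: Partition) -> list[tuple[int, int]]:
    """Match cluster pairs by descending contingency overlap, each used once.

    Ties break toward the lexicographically lowest (row, column) pair; the
    matching stops when every remaining overlap is zero.
    """
    table = np.zeros((p1.K, p2.K), dtype=int)
    np.add.at(table, (p1.labels, p2.labels), 1)
    table = table.astype(float)
    pairs: list[tuple[int, int]] = []
    while True:
        best = table.max()
        if best <= 0:
            break
        i, j = np.unravel_index(int(np.argmax(table)), table.shape)
        pairs.append((int(i), int(j)))
        table[i, :] = -1
        table[:, j] = -1
    return pairs


def _combined(view1: SimilarityView, view2: SimilarityView) -> np.ndarray:
    return (view1.matrix + view2.matrix) / 2.0


def _central_gene(members: np.ndarray, combined: np.ndarray) -> int:
    """Member maximizing mean combined similarity to the other members."""
    if len(members) == 1:
        return int(members[0])
    sub = combined[np.ix_(members, members)]
    np.fill_diagonal(sub, 0.0)
    avg = sub.sum(axis=1) / (len(members) - 1)
    # ties -> lowest gene index; members is sorted ascending by construction
    return int(members[int(np.argmax(avg))])


def build_consensus(
    sol: ParentSolution, view1: SimilarityView, view2: SimilarityView
) -> tuple[MedoidString, Partition]:
    """Merge the two view partitions into one consensus clustering.

    Greedily pairs maximally overlapping clusters of the two partitions;
    each matched pair's common genes form a consensus core whose medoid is
    the most centrally located common gene under the combined similarity
    (S1 + S2) / 2. Genes outside every core are assigned to the core with
    the highest mean combined similarity. When fewer than two matched pairs
    exist, the partition of the view string with the lower Xie-Beni index is
    copied as the consensus.
    """
    p1, p2 = sol.partition1, sol.partition2
    if p1 is None or p2 is None:
        raise ValueError("view partitions must be assigned before consensus")
    n = p1.n
    combined = _combined(view1, view2)
    pairs = _greedy_overlap_matching(p1, p2)
    cores: list[np.ndarray] = []
    for i, j in pairs:
        common = np.flatnonzero((p1.labels == i) & (p2.labels == j))
        if len(common):
            cores.append(common)
    if len(cores) < 2:
        # degenerate overlap: copy the stronger (lower-XB) view's clustering
        xb1 = xb_index(p1, sol.string1, view1)
        xb2 = xb_index(p2, sol.string2, view2)
        if xb1 <= xb2:
            return sol.string1, Partition(labels=p1.labels.copy(), K=p1.K)
        return sol.string2, Partition(labels=p2.labels.copy(), K=p2.K)

    medoids = tuple(_central_gene(core, combined) for core in cores)
    labels = np.full(n, -1, dtype=int)
    for k, core in enumerate(cores):
        labels[core] = k
    unassigned = np.flatnonzero(labels == -1)
    if len(unassigned):
        # mean combined similarity of every gene to each fixed core
        scores = np.column_stack(
            [combined[:, core].mean(axis=1) for core in cores]
        )
        labels[unassigned] = np.argmax(scores[unassigned], axis=1)
    return MedoidString(medoids), Partition(labels=labels, K=len(cores))


def xb_index(p: Partition, medoids: MedoidString, view: SimilarityView) -> float:
    """Crisp Xie-Beni index on dissimilarity d = 1 - S.

    XB = sum_k sum_{x in C_k} d(x, m_k)^2 / (n * min_{k != l} d(m_k, m_l)^2).
    Coincident medoids (zero separation) return the +inf sentinel.
    """
    if p.K < 2:
        raise ValueError("Xie-Beni needs at least 2 clusters")
    if medoids.K != p.K:
        raise ValueError("medoid string and partition disagree on K")
    d = view.dissimilarity()
    med = np.asarray(medoids.medoids, dtype=int)
    numerator = float(np.sum(d[np.arange(p.n), med[p.labels]] ** 2))
    sep = d[np.ix_(med, med)].copy()
    np.fill_diagonal(sep, np.inf)
    min_sep = float(sep.min())
    if min_sep == 0.0:
        return float("inf")
    return numerator / (p.n * min_sep**2)


def agreement_index(p1: Partition, p2: Partition) -> float:
    """AI = (AG + 1) / (DG + 1) over the two n x n co-membership matrices.

    AG counts positions (including the unit diagonal) where the two binary
    agreement matrices coincide; DG = n^2 - AG. Identical co-membership
    yields the maximum n^2 + 1; the +1 terms guard the division.
    """
    if p1.n != p2.n:
        raise ValueError("partitions cover different numbers of elements")
    same1 = p1.labels[:, None] == p1.labels[None, :]
    same2 = p2.labels[:, None] == p2.labels[None, :]
    ag = int(np.sum(same1 == same2))
    dg = p1.n**2 - ag
    return (ag + 1) / (dg + 1)


def evaluate(
    sol: ParentSolution, view1: SimilarityView, view2: SimilarityView
) -> ObjectiveVector:
    """Assign both view partitions, rebuild the consensus, score the solution.

    The objective vector is (XB view1, XB view2, AI), the first two
    minimized and the agreement maximized. The consensus string/partition
    are refreshed as a side effect so the archive always carries a current
    consensus.
    """
    sol.partition1 = assign_genes(sol.string1, view1)
    sol.partition2 = assign_genes(sol.string2, view2)
    sol.string3, sol.partition3 = build_consensus(sol, view1, view2)
    ov = ObjectiveVector(
        values=(
            xb_index(sol.partition1, sol.string1, view1),
            xb_index(sol.partition2, sol.string2, view2),
            agreement_index(sol.partition1, sol.partition2),
        ),
        directions=XB_DIRECTIONS,
    )
    sol.objectives = ov
    return ov


def _perturb_string(
    ms: MedoidString, op: int, n: int, rng: np.random.Generator
) -> MedoidString:
    med = list(ms.medoids)
    if op == 0:  # replace a random-position medoid with a random non-medoid gene
        pos = int(rng.integers(len(med)))
        choices = np.setdiff1d(np.arange(n), med, assume_unique=False)
        med[pos] = int(rng.choice(choices))
    elif op == 1:  # add a random non-medoid gene as a new medoid
        choices = np.setdiff1d(np.arange(n), med, assume_unique=False)
        med.append(int(rng.choice(choices)))
    else:  # delete the medoid at a random position
        med.pop(int(rng.integers(len(med))))
    return MedoidString(tuple(med))


def perturb(
    sol: ParentSolution,
    n: int,
    rng: np.random.Generator,
    strings: str = "single",
) -> ParentSolution:
    """Apply one operator (replace / add / delete) to a view string.

    The operator is drawn uniformly and re-drawn while it would push an
    affected string's K outside [2, floor(sqrt(n))]. With
    ``strings="single"`` (default) one of the two view strings is chosen
    uniformly and perturbed alone, so the annealer can improve one view
    without disturbing the other; ``strings="both"`` applies the same
    operator to both strings with independent random draws. The consensus
    string is never perturbed directly — it is rebuilt at the next
    evaluation.
    """
    kmax = k_max(n)
    if strings not in ("single", "both"):
        raise ValueError("strings must be 'single' or 'both'")

    if strings == "single":
        which = int(rng.integers(2))
        target = sol.string1 if which == 0 else sol.string2
        while True:
            op = int(rng.integers(3))
            if op == 1 and target.K + 1 > kmax:
                continue
            if op == 2 and target.K - 1 < 2:
                continue
            break
        new = _perturb_string(target, op, n, rng)
        return ParentSolution(
            string1=new if which == 0 else sol.string1,
            string2=new if which == 1 else sol.string2,
        )

    def feasible(op: int) -> bool:
        if op == 1:
            return sol.string1.K + 1 <= kmax and sol.string2.K + 1 <= kmax
        if op == 2:
            return sol.string1.K - 1 >= 2 and sol.string2.K - 1 >= 2
        return True

    op = int(rng.integers(3))
    while not feasible(op):
        op = int(rng.integers(3))
    return ParentSolution(
        string1=_perturb_string(sol.string1, op, n, rng),
        string2=_perturb_string(sol.string2, op, n, rng),
    )


class _ClusteringProblem:
    """Adapter binding the clustering moves to the annealing engine."""

    def __init__(self, view1: SimilarityView, view2: SimilarityView) -> None:
        self.view1 = view1
        self.view2 = view2
        self.n = view1.n

    def initial(self, rng: np.random.Generator) -> ParentSolution:
        return init_solution(self.n, rng)

    def perturb(self, sol: ParentSolution, rng: np.random.Generator) -> ParentSolution:
        return perturb(sol, self.n, rng)

    def evaluate(self, sol: ParentSolution) -> ObjectiveVector:
        if sol.objectives is None:
            evaluate(sol, self.view1, self.view2)
        assert sol.objectives is not None
        return sol.objectives


def run_cmvmc(
    view1: SimilarityView,
    view2: SimilarityView,
    cfg: AnnealConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Archive:
    """Anneal over parent solutions; returns the final non-dominated archive."""
    if view1.gene_ids != view2.gene_ids:
        raise ValueError("views are not aligned; run align_views first")
    cfg = cfg or AnnealConfig()
    rng = rng if rng is not None else np.random.default_rng()
    return anneal(_ClusteringProblem(view1, view2), cfg, rng)
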