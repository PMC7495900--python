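"""Internal/external cluster validity and downstream sample clustering.

Silhouette and Davies-Bouldin are implemented directly from their
definitions so they accept arbitrary precomputed dissimilarities (including
the 1 - similarity matrices the pipeline works on) and so the degenerate
conventions (singleton clusters, coincident centroids) are explicit.
Classification accuracy maps each cluster to its modal true class.

Sample clustering reuses the same annealing engine on a single view:
medoid clustering of the d samples on Euclidean dissimilarity of their
gene profiles, trading off the Xie-Beni index (minimized) against the mean
silhouette width (maximized); the reported partition is the archive member
with the best silhouette, since gene selections are ranked by how cleanly
the reduced matrix separates samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .amosa import AnnealConfig, ObjectiveVector, anneal
from .datamodel import ExpressionMatrix, Partition, SimilarityView
from .mvclust import MedoidString, assign_genes, k_max, xb_index


def silhouette(p: Partition, dissimilarity: np.ndarray) -> float:
    """Mean silhouette width over all points on a precomputed dissimilarity.

    For each point, a is its mean dissimilarity to co-members and b the
    smallest mean dissimilarity to any other cluster; the width is
    (b - a) / max(a, b). Singletons, and points with a = b = 0, contribute
    0.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if p.K < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    if d.shape != (p.n, p.n):
        raise ValueError("dissimilarity shape does not match partition")
    sizes = np.bincount(p.labels, minlength=p.K)
    # mean dissimilarity from every point to every cluster
    cluster_sums = np.zeros((p.n, p.K))
    for k in range(p.K):
        cluster_sums[:, k] = d[:, p.labels == k].sum(axis=1)
    widths = np.zeros(p.n)
    for i in range(p.n):
        k = p.labels[i]
        if sizes[k] == 1:
            continue
        a = cluster_sums[i, k] / (sizes[k] - 1)
        other = [cluster_sums[i, l] / sizes[l] for l in range(p.K) if l != k]
        b = min(other)
        m = max(a, b)
        widths[i] = 0.0 if m == 0.0 else (b - a) / m
    return float(widths.mean())


def davies_bouldin(
    p: Partition,
    points: np.ndarray | None = None,
    dissimilarity: np.ndarray | None = None,
) -> float:
    """DB = (1/K) sum_k max_{l != k} (sigma_k + sigma_l) / d(c_k, c_l).

    In vector mode (``points``) the centers are coordinate means and
    sigma_k the mean Euclidean distance of members to their center. In
    dissimilarity mode the centers are medoids (members minimizing total
    within-cluster dissimilarity). Coincident centers return the +inf
    sentinel.
    """
    if (points is None) == (dissimilarity is None):
        raise ValueError("pass exactly one of points or dissimilarity")
    if points is not None:
        x = np.asarray(points, dtype=float)
        centers = np.array([x[p.labels == k].mean(axis=0) for k in range(p.K)])
        sigma = np.array(
            [np.linalg.norm(x[p.labels == k] - centers[k], axis=1).mean()
             for k in range(p.K)]
        )
        center_d = squareform(pdist(centers))
    else:
        d = np.asarray(dissimilarity, dtype=float)
        medoids = []
        for k in range(p.K):
            idx = p.members(k)
            medoids.append(int(idx[np.argmin(d[np.ix_(idx, idx)].sum(axis=1))]))
        sigma = np.array(
            [d[p.members(k), medoids[k]].mean() for k in range(p.K)]
        )
        center_d = d[np.ix_(medoids, medoids)]
    db = 0.0
    for k in range(p.K):
        worst = -np.inf
        for l in range(p.K):
            if l == k:
                continue
            if center_d[k, l] == 0.0:
                return float("inf")
            worst = max(worst, (sigma[k] + sigma[l]) / center_d[k, l])
        db += worst
    return db / p.K


def classification_accuracy(
    p: Partition, labels: list | np.ndarray, mapping: str = "modal"
) -> float:
    """Percentage of elements whose cluster's assigned class matches their own.

    ``modal`` (default): each cluster is mapped to its most frequent true
    class, ties resolved toward the class occurring earliest (lowest
    element index) within the cluster. ``hungarian``: one-to-one optimal
    cluster-to-class assignment.
    """
    y = np.asarray(labels)
    if len(y) != p.n:
        raise ValueError("labels length does not match partition")
    classes, y_idx = np.unique(y, return_inverse=True)
    if mapping == "modal":
        correct = 0
        for k in range(p.K):
            members = p.members(k)
            counts = np.bincount(y_idx[members], minlength=len(classes))
            best = counts.max()
            tied = np.flatnonzero(counts == best)
            if len(tied) > 1:
                # earliest occurrence within the cluster wins
                first_pos = {c: int(np.flatnonzero(y_idx[members] == c)[0])
                             for c in tied}
                chosen = min(tied, key=lambda c: first_pos[c])
            else:
                chosen = tied[0]
            correct += int(counts[chosen])
    elif mapping == "hungarian":
        cont = np.zeros((p.K, len(classes)), dtype=int)
        np.add.at(cont, (p.labels, y_idx), 1)
        rows, cols = linear_sum_assignment(-cont)
        correct = int(cont[rows, cols].sum())
    else:
        raise ValueError("mapping must be 'modal' or 'hungarian'")
    return 100.0 * correct / p.n


def adjusted_rand(p1: Partition, p2: Partition) -> float:
    """Chance-corrected partition agreement (standard ARI)."""
    if p1.n != p2.n:
        raise ValueError("partitions cover different numbers of elements")
    return float(adjusted_rand_score(p1.labels, p2.labels))


@dataclass
class _SampleSolution:
    string: MedoidString
    partition: Partition | None = None
    objectives: ObjectiveVector | None = None


class _SampleProblem:
    """Single-view medoid clustering of samples for the annealing engine."""

    def __init__(self, dissimilarity: np.ndarray) -> None:
        self.d = dissimilarity
        self.n = dissimilarity.shape[0]
        dmax = dissimilarity.max()
        scaled = dissimilarity / dmax if dmax > 0 else dissimilarity
        self.view = SimilarityView(
            [f"s{i}" for i in range(self.n)], 1.0 - scaled
        )

    def initial(self, rng: np.random.Generator) -> _SampleSolution:
        kmax = k_max(self.n)
        k = int(rng.integers(2, kmax + 1)) if kmax > 2 else 2
        meds = tuple(int(x) for x in rng.choice(self.n, size=k, replace=False))
        return _SampleSolution(MedoidString(meds))

    def perturb(self, sol: _SampleSolution, rng: np.random.Generator) -> _SampleSolution:
        kmax = k_max(self.n)
        med = list(sol.string.medoids)
        while True:
            op = int(rng.integers(3))
            if op == 1 and len(med) + 1 > kmax:
                continue
            if op == 2 and len(med) - 1 < 2:
                continue
            break
        if op == 0:
            pos = int(rng.integers(len(med)))
            med[pos] = int(rng.choice(np.setdiff1d(np.arange(self.n), med)))
        elif op == 1:
            med.append(int(rng.choice(np.setdiff1d(np.arange(self.n), med))))
        else:
            med.pop(int(rng.integers(len(med))))
        return _SampleSolution(MedoidString(tuple(med)))

    def evaluate(self, sol: _SampleSolution) -> ObjectiveVector:
        if sol.objectives is None:
            p = assign_genes(sol.string, self.view)
            sol.partition = p
            sol.objectives = ObjectiveVector(
                values=(xb_index(p, sol.string, self.view), silhouette(p, self.d)),
                directions=("min", "max"),
            )
        return sol.objectives


def cluster_samples(
    em: ExpressionMatrix,
    cfg: AnnealConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Partition, float]:
    """Cluster the d samples of (typically reduced) expression data.

    Medoid clustering on Euclidean dissimilarity between sample profiles,
    annealed under (Xie-Beni minimized, silhouette maximized) with
    K in [2, floor(sqrt(d))]. Returns the archive member with the best
    silhouette together with that silhouette value.
    """
    if em.n_samples < 4:
        raise ValueError("need at least 4 samples to cluster")
    cfg = cfg or AnnealConfig()
    rng = rng if rng is not None else np.random.default_rng()
    d = squareform(pdist(em.values.T, metric="euclidean"))
    archive = anneal(_SampleProblem(d), cfg, rng)
    best, best_sil = None, -math.inf
    for sol in archive.solutions():
        assert sol.partition is not None and sol.objectives is not None
        sil = sol.objectives.values[1]
        if sil > best_sil:
            best, best_sil = sol.partition, sil
    assert best is not None
    return best, float(best_sil)
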