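"""Two-view synthetic data with planted gene clusters and sample classes.

The generator emulates the shape of data the selection pipeline consumes: a
genes x samples expression matrix whose signal genes fall into K* planted
co-expressed clusters with sample-class-dependent prototype profiles, plus
a second, expression-independent similarity view that is block-structured
around the same planted clusters at a tunable concordance rho.

A configurable fraction of genes are pure-noise features: their expression
is uniform, they get no coherent block in the second view, and the planted
truth assigns them to a designated extra "noise" cluster (label K*). They
model the irrelevant/redundant genes the selection step should avoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import ExpressionMatrix, Partition, SimilarityView

#: similarity level drawn within a planted block
_HIGH = (0.7, 0.9)
#: background similarity between blocks and for noise genes
_LOW = (0.1, 0.3)


@dataclass
class SyntheticParams:
    """Study conditions for one synthetic data set.

    ``n`` genes x ``d`` samples; ``k_star`` planted gene clusters;
    ``sigma`` within-cluster expression noise (sd of the Gaussian around
    each prototype, on the 0-1 prototype scale); ``rho`` the concordance of
    the second view with the planted partition (the fraction of genes whose
    block rows survive; the rest are resampled to random levels);
    ``noise_frac`` the fraction of genes that are pure-noise features;
    ``n_sample_classes`` planted sample classes of near-equal size.
    """

    n: int = 120
    d: int = 20
    k_star: int = 4
    sigma: float = 0.1
    rho: float = 0.9
    noise_frac: float = 0.3
    n_sample_classes: int = 4
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Planted structure behind one generated data set."""

    gene_partition: Partition
    sample_partition: Partition
    params: SyntheticParams
    noise_label: int | None = None
    signal_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def signal_partition(self) -> Partition:
        """Planted partition restricted to the signal (non-noise) genes."""
        return Partition(labels=self.gene_partition.labels[self.signal_genes])


def generate(
    params: SyntheticParams, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, SimilarityView, SyntheticTruth]:
    """Generate (expression matrix, second-view similarity, planted truth).

    Signal gene i of planted cluster k has expression
    ``prototype[k, class(sample)] + N(0, sigma)``; prototypes place each
    cluster at a distinct pair of levels across sample classes so both the
    gene clusters and the sample classes are recoverable in the noiseless
    limit. Noise genes are Uniform(0, 1) throughout. The second view is
    high (Uniform 0.7-0.9) within a planted block and low (Uniform
    0.1-0.3) elsewhere; a fraction (1 - rho) of genes then have their
    rows/columns resampled to random levels, and noise genes never receive
    a block.
    """
    p = params
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    if p.k_star > int(np.sqrt(p.n)):
        raise ValueError(
            f"k_star={p.k_star} exceeds floor(sqrt(n))={int(np.sqrt(p.n))}; "
            "the medoid encoding cannot represent the truth"
        )
    if not 0.0 <= p.rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if not 0.0 <= p.noise_frac < 1.0:
        raise ValueError("noise_frac must lie in [0, 1)")

    n_noise = int(round(p.noise_frac * p.n))
    n_signal = p.n - n_noise
    if n_signal < 2 * p.k_star:
        raise ValueError("too few signal genes for the requested k_star")

    # planted gene partition: contiguous blocks, noise genes last (label K*)
    gene_labels = np.empty(p.n, dtype=int)
    sizes = np.full(p.k_star, n_signal // p.k_star)
    sizes[: n_signal % p.k_star] += 1
    start = 0
    for k, size in enumerate(sizes):
        gene_labels[start : start + size] = k
        start += size
    noise_label = None
    if n_noise:
        noise_label = p.k_star
        gene_labels[n_signal:] = noise_label
    signal_genes = np.arange(n_signal)

    # planted sample classes, near-equal sizes
    sample_labels = np.sort(np.arange(p.d) % p.n_sample_classes)

    # prototype expression per (gene cluster, sample class). One-hot
    # patterns (cluster k "on" in class k mod nc) keep all between-cluster
    # distances equal when nc >= K*, so no merge of planted clusters is
    # cheaper than any other; binary on/off codes are the fallback, and
    # graded levels the last resort for many clusters over few classes.
    nc = p.n_sample_classes
    if nc >= p.k_star:
        proto = np.array(
            [[1.0 if c == k % nc else 0.0 for c in range(nc)]
             for k in range(p.k_star)]
        )
    elif p.k_star <= 2**nc:
        proto = np.array(
            [[(k >> c) & 1 for c in range(nc)] for k in range(p.k_star)],
            dtype=float,
        )
    else:
        levels = np.linspace(0.0, 1.0, p.k_star)
        proto = np.array(
            [[levels[(k + c) % p.k_star] for c in range(nc)]
             for k in range(p.k_star)]
        )

    values = np.empty((p.n, p.d))
    for i in range(n_signal):
        base = proto[gene_labels[i], sample_labels]
        values[i] = base + (rng.normal(0.0, p.sigma, size=p.d) if p.sigma > 0 else 0.0)
    if n_noise:
        # bounded uniform over the prototype range: class-structure-free
        # background features; expression-wise they hover around mid-range,
        # so the pipeline isolates them as the designated noise cluster
        # rather than letting them contaminate the co-expressed clusters
        values[n_signal:] = rng.uniform(0.0, 1.0, size=(n_noise, p.d))

    # second view: block similarity following the full planted partition
    # (the designated noise cluster is a block too — functionally the noise
    # genes are a coherent "irrelevant background" module)
    s = rng.uniform(*_LOW, size=(p.n, p.n))
    same = gene_labels[:, None] == gene_labels[None, :]
    s[same] = rng.uniform(*_HIGH, size=int(same.sum()))
    # discord: (1 - rho) of the genes lose their block structure entirely
    n_discord = int(round((1.0 - p.rho) * p.n))
    if n_discord:
        victims = rng.choice(p.n, size=n_discord, replace=False)
        noise_rows = rng.uniform(_LOW[0], _HIGH[1], size=(n_discord, p.n))
        s[victims, :] = noise_rows
        s[:, victims] = noise_rows.T
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)

    gene_ids = [f"g{i:04d}" for i in range(p.n)]
    em = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[f"s{j:03d}" for j in range(p.d)],
        values=values,
        sample_labels=[f"class{c}" for c in sample_labels],
    )
    view2 = SimilarityView(gene_ids, s)
    truth = SyntheticTruth(
        gene_partition=Partition(labels=gene_labels),
        sample_partition=Partition(labels=sample_labels),
        params=p,
        noise_label=noise_label,
        signal_genes=signal_genes,
    )
    return em, view2, truth


def perturb_partition(
    p: Partition, fraction: float, rng: np.random.Generator
) -> Partition:
    """Reassign ceil(fraction * n) random elements to random other clusters.

    K is preserved: victim/move draws that would empty a cluster are
    re-drawn (up to a bounded number of attempts; an irreducibly emptying
    draw at extreme fractions falls back to accepting the K reduction with
    relabeled clusters).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return Partition(labels=p.labels.copy(), K=p.K)
    m = int(np.ceil(fraction * p.n))
    for _ in range(100):
        labels = p.labels.copy()
        victims = rng.choice(p.n, size=m, replace=False)
        for v in victims:
            others = [k for k in range(p.K) if k != labels[v]]
            labels[v] = others[int(rng.integers(len(others)))]
        if len(np.unique(labels)) == p.K:
            return Partition(labels=labels, K=p.K)
    # degenerate: accept the K reduction, compacting labels to 0..K'-1
    _, labels = np.unique(labels, return_inverse=True)
    return Partition(labels=labels)
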