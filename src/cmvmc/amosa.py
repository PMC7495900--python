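"""Archived Multi-Objective Simulated Annealing (AMOSA).

A generic engine over a user-supplied problem object exposing

    initial(rng)      -> solution
    perturb(s, rng)   -> solution
    evaluate(s)       -> ObjectiveVector

The engine owns Pareto domination, the temperature- and
domination-amount-dependent acceptance rule, and a bounded archive of
mutually non-dominated solutions. Whenever the archive exceeds its soft
limit it is pruned to the hard limit by single-linkage clustering of the
objective vectors, keeping one representative (the member closest to its
cluster centroid) per cluster.

All components are internally converted to minimization (maximized
components are negated); the public ``values`` on :class:`ObjectiveVector`
keeps the user's original orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger("cmvmc")

_INF = float("inf")


@dataclass(frozen=True)
class ObjectiveVector:
    """Fixed-length objective tuple with per-component optimization direction."""

    values: tuple[float, ...]
    directions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.directions):
            raise ValueError("values and directions differ in length")
        if any(d not in ("min", "max") for d in self.directions):
            raise ValueError("directions must be 'min' or 'max'")

    @property
    def minimized(self) -> tuple[float, ...]:
        """Components on a common minimization scale (max components negated)."""
        return tuple(-v if d == "max" else v
                     for v, d in zip(self.values, self.directions))


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """Pareto domination: a no worse everywhere, strictly better somewhere."""
    if a.directions != b.directions:
        raise ValueError("objective vectors have different directions/lengths")
    av, bv = a.minimized, b.minimized
    return all(x <= y for x, y in zip(av, bv)) and any(x < y for x, y in zip(av, bv))


def domination_amount(
    a: ObjectiveVector, b: ObjectiveVector, ranges: Sequence[float]
) -> float:
    """Product over differing objectives of the range-normalized gap.

    Only objectives where ``a`` and ``b`` differ enter the product; equal
    vectors give 0. Ranges of 0 (degenerate, single observed value) fall
    back to 1 so the factor is the raw gap.
    """
    av, bv = a.minimized, b.minimized
    if len(ranges) != len(av):
        raise ValueError("ranges length mismatch")
    amount = 1.0
    any_diff = False
    for x, y, r in zip(av, bv, ranges):
        if x != y:
            any_diff = True
            amount *= abs(x - y) / (r if r > 0 else 1.0)
    return amount if any_diff else 0.0


@dataclass
class _Member:
    solution: Any
    objectives: ObjectiveVector
    order: int  # insertion counter, used for deterministic prune tie-breaks


@dataclass
class Archive:
    """Bounded set of mutually non-dominated solutions."""

    soft_limit: int = 40
    hard_limit: int = 20
    members: list[_Member] = field(default_factory=list)
    _counter: int = 0

    def __len__(self) -> int:
        return len(self.members)

    def solutions(self) -> list[Any]:
        return [m.solution for m in self.members]

    def objective_vectors(self) -> list[ObjectiveVector]:
        return [m.objectives for m in self.members]

    def insert(self, solution: Any, objectives: ObjectiveVector) -> bool:
        """Insert keeping pairwise non-domination; prune to HL past SL.

        Returns False when the newcomer is dominated by (or duplicates) an
        existing member and is rejected.
        """
        for m in self.members:
            if dominates(m.objectives, objectives) or (
                m.objectives.minimized == objectives.minimized
            ):
                return False
        self.members = [m for m in self.members
                        if not dominates(objectives, m.objectives)]
        self.members.append(_Member(solution, objectives, self._counter))
        self._counter += 1
        if len(self.members) > self.soft_limit:
            self._prune()
        return True

    def _prune(self) -> None:
        """Single-linkage clustering of objective vectors down to HL members."""
        vecs = np.array([m.objectives.minimized for m in self.members], dtype=float)
        finite = np.isfinite(vecs)
        if not finite.all():
            # clamp infinities to the observed finite extreme so linkage works
            col_max = np.where(finite, vecs, -np.inf).max(axis=0)
            col_max = np.where(np.isfinite(col_max), col_max, 1.0)
            vecs = np.where(finite, vecs, col_max[None, :] * 10 + 1)
        z = linkage(pdist(vecs), method="single")
        # cut_tree yields exactly hard_limit clusters even on tied merge heights
        labels = cut_tree(z, n_clusters=self.hard_limit).ravel()
        kept: list[_Member] = []
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            centroid = vecs[idx].mean(axis=0)
            dist = np.linalg.norm(vecs[idx] - centroid, axis=1)
            best = min(range(len(idx)),
                       key=lambda i: (dist[i], self.members[idx[i]].order))
            kept.append(self.members[idx[best]])
        kept.sort(key=lambda m: m.order)
        self.members = kept


@dataclass
class AnnealConfig:
    """Cooling schedule and archive bounds.

    Defaults are ordinary simulated-annealing magnitudes: a geometric
    schedule from ``tmax`` to ``tmin`` with factor ``alpha`` and
    ``iters_per_temp`` moves per level; archive soft/hard limits control
    how many non-dominated solutions survive to the ensemble stage.
    """

    tmax: float = 100.0
    tmin: float = 1e-4
    alpha: float = 0.9
    iters_per_temp: int = 50
    soft_limit: int = 40
    hard_limit: int = 20
    n_initial: int = 10

    def __post_init__(self) -> None:
        if not (self.tmax >= self.tmin > 0):
            raise ValueError("need tmax >= tmin > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("cooling factor alpha must be in (0, 1)")
        if self.iters_per_temp < 1:
            raise ValueError("iters_per_temp must be >= 1")
        if self.hard_limit > self.soft_limit:
            raise ValueError("hard_limit cannot exceed soft_limit")

    def temperatures(self) -> list[float]:
        temps = []
        t = self.tmax
        while t >= self.tmin:
            temps.append(t)
            t *= self.alpha
        return temps or [self.tmax]


def _accept_probability(delta_dom: float, temperature: float) -> float:
    x = delta_dom / temperature
    if x > 700:
        return 0.0
    return 1.0 / (1.0 + math.exp(x))


class _RangeTracker:
    """Running per-objective min/max over every vector seen in the run."""

    def __init__(self, m: int) -> None:
        self.lo = [_INF] * m
        self.hi = [-_INF] * m

    def update(self, ov: ObjectiveVector) -> None:
        for i, v in enumerate(ov.minimized):
            if math.isfinite(v):
                self.lo[i] = min(self.lo[i], v)
                self.hi[i] = max(self.hi[i], v)

    @property
    def ranges(self) -> list[float]:
        return [h - l if math.isfinite(h - l) and h > l else 1.0
                for l, h in zip(self.lo, self.hi)]


def anneal(problem: Any, cfg: AnnealConfig, rng: np.random.Generator) -> Archive:
    """Run AMOSA and return the final archive.

    Acceptance of a move dominated (on average) by ``delta`` uses
    probability ``1 / (1 + exp(delta / T))``; the archive is updated
    according to the standard case analysis on how the new point relates to
    the current point and to the archive.
    """
    archive = Archive(soft_limit=cfg.soft_limit, hard_limit=cfg.hard_limit)
    tracker: _RangeTracker | None = None

    # seed the archive with evaluated random solutions, pruned by domination
    seeds = []
    attempts = 0
    while len(seeds) < max(1, cfg.n_initial) and attempts < 10 * cfg.n_initial + 10:
        attempts += 1
        try:
            s = problem.initial(rng)
            ov = problem.evaluate(s)
        except Exception:  # noqa: BLE001 - a bad draw must not kill the run
            logger.exception("initial solution evaluation failed; discarded")
            continue
        seeds.append((s, ov))
        if tracker is None:
            tracker = _RangeTracker(len(ov.values))
        tracker.update(ov)
    if tracker is None:
        raise RuntimeError("could not evaluate any initial solution")
    for s, ov in seeds:
        archive.insert(s, ov)

    idx = int(rng.integers(len(archive)))
    current, current_ov = archive.members[idx].solution, archive.members[idx].objectives

    for temperature in cfg.temperatures():
        for _ in range(cfg.iters_per_temp):
            try:
                new = problem.perturb(current, rng)
                new_ov = problem.evaluate(new)
            except Exception:  # noqa: BLE001 - a bad move must not kill the run
                logger.exception("perturbation evaluation failed; move discarded")
                continue
            tracker.update(new_ov)
            ranges = tracker.ranges
            arch_ovs = archive.objective_vectors()
            dominating = [ov for ov in arch_ovs if dominates(ov, new_ov)]

            if dominates(current_ov, new_ov):
                # case 1: new dominated by current (and possibly the archive)
                doms = [domination_amount(ov, new_ov, ranges) for ov in dominating]
                doms.append(domination_amount(current_ov, new_ov, ranges))
                delta = sum(doms) / len(doms)
                if rng.random() < _accept_probability(delta, temperature):
                    current, current_ov = new, new_ov
            elif dominates(new_ov, current_ov):
                # case 3: new dominates current
                if dominating:
                    amounts = [domination_amount(ov, new_ov, ranges)
                               for ov in dominating]
                    k = int(np.argmin(amounts))
                    if rng.random() < 1.0 / (1.0 + math.exp(-amounts[k])):
                        member = next(m for m in archive.members
                                      if m.objectives is dominating[k])
                        current, current_ov = member.solution, member.objectives
                    else:
                        current, current_ov = new, new_ov
                else:
                    archive.insert(new, new_ov)
                    current, current_ov = new, new_ov
            else:
                # case 2: current and new mutually non-dominating
                if dominating:
                    delta = sum(domination_amount(ov, new_ov, ranges)
                                for ov in dominating) / len(dominating)
                    if rng.random() < _accept_probability(delta, temperature):
                        current, current_ov = new, new_ov
                else:
                    archive.insert(new, new_ov)
                    current, current_ov = new, new_ov
    return archive
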