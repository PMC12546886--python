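"""NSGA-II machinery: Pareto dominance, fast nondominated sorting,
crowding distance, the nondominated archive, and exact hypervolume."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass(eq=False)
class Individual:
    x: np.ndarray
    objectives: Optional[np.ndarray] = None
    rank: Optional[int] = None
    crowding: Optional[float] = None

    def copy(self) -> "Individual":
        return Individual(
            x=self.x.copy(),
            objectives=None if self.objectives is None else self.objectives.copy(),
            rank=self.rank,
            crowding=self.crowding,
        )


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Pareto dominance (minimization): a <= b everywhere, < somewhere."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("objective vectors have mismatched lengths")
    return bool(np.all(a <= b) and np.any(a < b))


def nondominated_sort(population: list[Individual]) -> list[list[Individual]]:
    """Deb's fast nondominated sort; sets ``rank`` (1-based) on members."""
    if not population:
        raise ValueError("population must be nonempty")
    objs = []
    for ind in population:
        if ind.objectives is None:
            raise ValueError("unevaluated individual in population")
        objs.append(np.asarray(ind.objectives, dtype=float))
    F = np.stack(objs)
    n = len(population)
    # pairwise dominance via broadcasting
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    dominated_by = [np.flatnonzero(dom[i]) for i in range(n)]

    fronts: list[list[int]] = []
    current = list(np.flatnonzero(n_dominators == 0))
    counts = n_dominators.copy()
    while current:
        fronts.append(current)
        nxt: list[int] = []
        for i in current:
            for j in dominated_by[i]:
                counts[j] -= 1
                if counts[j] == 0:
                    nxt.append(int(j))
        current = sorted(nxt)
    out = []
    for r, idxs in enumerate(fronts, start=1):
        front = [population[i] for i in idxs]
        for ind in front:
            ind.rank = r
        out.append(front)
    return out


def crowding_distance(front: list[Individual]) -> np.ndarray:
    """NSGA-II crowding distance; sets ``crowding`` on members.

    Fronts of fewer than three members get all-infinite distances.
    """
    n = len(front)
    if n == 0:
        return np.array([])
    dist = np.zeros(n)
    if n < 3:
        dist[:] = np.inf
    else:
        F = np.stack([ind.objectives for ind in front])
        for m in range(F.shape[1]):
            order = np.argsort(F[:, m], kind="stable")
            fmin, fmax = F[order[0], m], F[order[-1], m]
            dist[order[0]] = dist[order[-1]] = np.inf
            if fmax > fmin:
                gaps = (F[order[2:], m] - F[order[:-2], m]) / (fmax - fmin)
                dist[order[1:-1]] += gaps
    for ind, d in zip(front, dist):
        ind.crowding = float(d)
    return dist


def environmental_selection(population: list[Individual], size: int) -> list[Individual]:
    """NSGA-II survivor selection: fill whole fronts, split the last by
    descending crowding distance."""
    survivors: list[Individual] = []
    for front in nondominated_sort(population):
        crowding_distance(front)
        if len(survivors) + len(front) <= size:
            survivors.extend(front)
        else:
            need = size - len(survivors)
            order = sorted(range(len(front)), key=lambda i: -front[i].crowding)
            survivors.extend(front[i] for i in order[:need])
            break
    return survivors


# ---------------------------------------------------------------------------
# hypervolume


def _hv2d(points: np.ndarray, ref: np.ndarray) -> float:
    """Exact 2-D hypervolume by a sorted sweep; tolerates dominated points."""
    keep = np.all(points < ref, axis=1)
    pts = points[keep]
    if len(pts) == 0:
        return 0.0
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    hv = 0.0
    prev_y = ref[1]
    for x, y in pts:
        if y < prev_y:
            hv += (ref[0] - x) * (prev_y - y)
            prev_y = y
    return float(hv)


def hypervolume(front, ref_point) -> float:
    """Lebesgue measure of the region dominated by ``front`` and bounded by
    ``ref_point``.  Exact sweep for two objectives, slab-wise recursive
    slicing for three.  Points not strictly dominating the reference point
    are rejected; dominated points contribute nothing.
    """
    F = np.asarray(
        [ind.objectives if isinstance(ind, Individual) else ind for ind in front], dtype=float
    )
    ref = np.asarray(ref_point, dtype=float)
    if F.ndim != 2 or F.shape[1] != ref.shape[0]:
        raise ValueError("front/reference dimension mismatch")
    if np.any(F >= ref):
        raise ValueError("every front member must strictly dominate the reference point")
    m = F.shape[1]
    if m == 2:
        return _hv2d(F, ref)
    if m == 3:
        order = np.argsort(F[:, 2], kind="stable")
        F = F[order]
        zs = F[:, 2]
        hv = 0.0
        levels = np.unique(zs)
        for i, z in enumerate(levels):
            z_next = levels[i + 1] if i + 1 < len(levels) else ref[2]
            active = F[zs <= z][:, :2]
            hv += _hv2d(active, ref[:2]) * (z_next - z)
        return float(hv)
    raise NotImplementedError("hypervolume implemented for 2 or 3 objectives")


def hypervolume_monte_carlo(front, ref_point, n_samples: int, rng: np.random.Generator) -> float:
    """Independent Monte-Carlo estimator used as a cross-check oracle."""
    F = np.asarray(
        [ind.objectives if isinstance(ind, Individual) else ind for ind in front], dtype=float
    )
    ref = np.asarray(ref_point, dtype=float)
    lo = F.min(axis=0)
    box = np.prod(ref - lo)
    samples = rng.uniform(lo, ref, size=(n_samples, len(ref)))
    covered = np.zeros(n_samples, dtype=bool)
    for f in F:
        covered |= np.all(samples >= f, axis=1)
    return float(box * covered.mean())


# ---------------------------------------------------------------------------
# archive


@dataclass
class ParetoArchive:
    """Bounded nondominated archive with crowding-based truncation."""

    capacity: int = 100
    members: list[Individual] = field(default_factory=list)

    def update(self, candidates: Sequence[Individual]) -> None:
        pool = self.members + [c.copy() for c in candidates]
        if not pool:
            return
        fronts = nondominated_sort(pool)
        front = fronts[0]
        # drop exact duplicates in objective space (keep first)
        seen: set[tuple] = set()
        unique = []
        for ind in front:
            key = tuple(np.round(ind.objectives, 12))
            if key not in seen:
                seen.add(key)
                unique.append(ind)
        if len(unique) > self.capacity:
            crowding_distance(unique)
            order = sorted(range(len(unique)), key=lambda i: -unique[i].crowding)
            unique = [unique[i] for i in order[: self.capacity]]
        for ind in unique:
            ind.rank = 1
        crowding_distance(unique)
        self.members = unique

    def hypervolume(self, ref_point) -> float:
        ref = np.asarray(ref_point, dtype=float)
        pts = [m.objectives for m in self.members if np.all(m.objectives < ref)]
        if not pts:
            return 0.0
        return hypervolume(pts, ref)

    def sample_guide(self, rng: np.random.Generator) -> Individual:
        """Crowding-biased roulette draw (boundary members favoured)."""
        if not self.members:
            raise ValueError("empty archive")
        crowding_distance(self.members)
        w = np.array([m.crowding for m in self.members])
        finite = w[np.isfinite(w)]
        cap = 2.0 * finite.max() if finite.size and finite.max() > 0 else 1.0
        w = np.where(np.isfinite(w), w, cap) + 1e-12
        idx = rng.choice(len(self.members), p=w / w.sum())
        return self.members[int(idx)]

    def best_by_objective(self, index: int = 0) -> Individual:
        return min(self.members, key=lambda m: m.objectives[index])

    def __len__(self) -> int:
        return len(self.members)
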