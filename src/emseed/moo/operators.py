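"""Variation and selection operators: tournament selection, simulated
binary crossover, polynomial mutation, and the PSO velocity/position
update with linearly decaying inertia."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Individual


def _sort_key(ind: Individual):
    rank = ind.rank if ind.rank is not None else 1
    crowd = ind.crowding if ind.crowding is not None else 0.0
    return (rank, -crowd)


def tournament_select(
    population: list[Individual], k: int, rng: np.random.Generator
) -> Individual:
    """Best of ``k`` draws without replacement under the (rank, -crowding)
    lexicographic order; ties resolved by draw order (uniform among equals)."""
    if k > len(population):
        raise ValueError("tournament size exceeds population")
    idxs = rng.choice(len(population), size=k, replace=False)
    best = population[int(idxs[0])]
    for i in idxs[1:]:
        cand = population[int(i)]
        if _sort_key(cand) < _sort_key(best):
            best = cand
    return best


def sbx_crossover(
    p1: np.ndarray,
    p2: np.ndarray,
    prob: float,
    eta_c: float,
    rng: np.random.Generator,
    bounds: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover (bounded), mean-preserving per gene in
    expectation.  With probability 1-prob the parents are copied."""
    lo, hi = bounds
    c1, c2 = p1.astype(float).copy(), p2.astype(float).copy()
    if rng.random() >= prob:
        return c1, c2
    for j in range(len(p1)):
        if rng.random() > 0.5 or abs(p1[j] - p2[j]) < 1e-14:
            continue
        u = rng.random()
        if u <= 0.5:
            beta = (2.0 * u) ** (1.0 / (eta_c + 1.0))
        else:
            beta = (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta_c + 1.0))
        a = 0.5 * ((1.0 + beta) * p1[j] + (1.0 - beta) * p2[j])
        b = 0.5 * ((1.0 - beta) * p1[j] + (1.0 + beta) * p2[j])
        if rng.random() < 0.5:
            a, b = b, a
        c1[j], c2[j] = a, b
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def polynomial_mutation(
    x: np.ndarray,
    prob: float,
    eta_m: float,
    rng: np.random.Generator,
    bounds: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Deb's bounded polynomial mutation, applied gene-wise with
    probability ``prob``."""
    lo, hi = bounds
    out = x.astype(float).copy()
    span = hi - lo
    for j in range(len(x)):
        if rng.random() >= prob:
            continue
        u = rng.random()
        delta1 = (out[j] - lo[j]) / span[j]
        delta2 = (hi[j] - out[j]) / span[j]
        mut_pow = 1.0 / (eta_m + 1.0)
        if u < 0.5:
            xy = 1.0 - delta1
            val = 2.0 * u + (1.0 - 2.0 * u) * xy ** (eta_m + 1.0)
            delta_q = val**mut_pow - 1.0
        else:
            xy = 1.0 - delta2
            val = 2.0 * (1.0 - u) + 2.0 * (u - 0.5) * xy ** (eta_m + 1.0)
            delta_q = 1.0 - val**mut_pow
        out[j] = out[j] + delta_q * span[j]
    return np.clip(out, lo, hi)


@dataclass
class Particle:
    x: np.ndarray
    v: np.ndarray
    pbest_x: np.ndarray
    pbest_obj: Optional[np.ndarray] = None
    objectives: Optional[np.ndarray] = None


def inertia_weight(it: int, max_iter: int, start: float = 0.9, end: float = 0.4) -> float:
    """Linear decay from ``start`` to ``end`` over the run."""
    if max_iter <= 0:
        return start
    return start - (start - end) * it / max_iter


def pso_step(
    particle: Particle,
    guide: np.ndarray,
    it: int,
    max_iter: int,
    c1: float,
    c2: float,
    rng: np.random.Generator,
    bounds: tuple[np.ndarray, np.ndarray],
    v_max_fraction: float = 0.2,
    inertia_start: float = 0.9,
    inertia_end: float = 0.4,
) -> Particle:
    """One velocity/position update; velocity clamped componentwise to
    ``v_max_fraction`` of each variable's range, position clipped to bounds."""
    if it > max_iter:
        raise ValueError("iteration beyond max_iter")
    lo, hi = bounds
    v_max = v_max_fraction * (hi - lo)
    w = inertia_weight(it, max_iter, inertia_start, inertia_end)
    r1 = rng.random(len(particle.x))
    r2 = rng.random(len(particle.x))
    v = (
        w * particle.v
        + c1 * r1 * (particle.pbest_x - particle.x)
        + c2 * r2 * (guide - particle.x)
    )
    v = np.clip(v, -v_max, v_max)
    x = np.clip(particle.x + v, lo, hi)
    particle.v = v
    particle.x = x
    particle.objectives = None
    return particle
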