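"""Cooperative-coevolution hybrid GA-PSO runner plus plain NSGA-II and a
Tchebycheff-decomposition baseline.

A GA population (NSGA-II machinery) and a particle swarm evolve
simultaneously against one shared nondominated archive.  Swarm guides are
drawn from the archive by crowding-biased roulette; every few iterations
the best archive members migrate into both populations.  Rates adapt
on-line from the hypervolume/diversity history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    Individual,
    ParetoArchive,
    crowding_distance,
    dominates,
    environmental_selection,
    nondominated_sort,
)
from .operators import Particle, polynomial_mutation, pso_step, sbx_crossover, tournament_select
from .scalar import AdaptRatesConfig, Rates, adapt_rates


@dataclass
class HybridConfig:
    ga_pop_size: int = 50
    crossover_p: float = 0.8
    mutation_p: float = 0.02
    tournament_k: int = 3
    eta_c: float = 15.0
    eta_m: float = 20.0
    swarm_size: int = 30
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    v_max_fraction: float = 0.2
    migration_interval: int = 10
    migration_count: int = 5
    archive_capacity: int = 200
    max_iters: int = 100
    rng_seed: int = 0
    adapt: AdaptRatesConfig = field(default_factory=AdaptRatesConfig)

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_p <= 1 and 0 <= self.mutation_p <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.ga_pop_size < 2 or self.swarm_size < 2:
            raise ValueError("population sizes must be >= 2")


class OptimizationAborted(RuntimeError):
    """Raised when an objective evaluation fails mid-run; carries the
    checkpointed archive/history and a fallback decision vector."""

    def __init__(self, message, archive, history, fallback_x):
        super().__init__(message)
        self.archive = archive
        self.history = history
        self.fallback_x = fallback_x


def _init_reference(objs: list[np.ndarray]) -> np.ndarray:
    F = np.stack(objs)
    worst = F.max(axis=0)
    best = F.min(axis=0)
    span = np.maximum(worst - best, 1e-9)
    return worst + 0.1 * span + 1e-9


def _rank_population(pop: list[Individual]) -> None:
    for front in nondominated_sort(pop):
        crowding_distance(front)


def migrate(
    ga_population: list[Individual],
    swarm: list[Particle],
    archive: ParetoArchive,
    count: int,
) -> tuple[list[Individual], list[Particle]]:
    """Copy the ``count`` most spread archive members into both populations,
    replacing the worst GA members and the worst swarm personal bests.
    The archive itself is unchanged."""
    if count == 0 or len(archive) == 0:
        return ga_population, swarm
    count = min(count, len(archive), len(ga_population), len(swarm))
    crowding_distance(archive.members)
    elites = sorted(
        archive.members,
        key=lambda m: -(m.crowding if m.crowding is not None else 0.0),
    )[:count]

    _rank_population(ga_population)
    ga_order = sorted(
        range(len(ga_population)),
        key=lambda i: (ga_population[i].rank, -(ga_population[i].crowding or 0.0)),
    )
    for slot, elite in zip(ga_order[::-1], elites):
        ga_population[slot] = elite.copy()

    pb = [Individual(x=p.pbest_x, objectives=p.pbest_obj) for p in swarm]
    _rank_population(pb)
    pb_order = sorted(range(len(pb)), key=lambda i: (pb[i].rank, -(pb[i].crowding or 0.0)))
    for slot, elite in zip(pb_order[::-1], elites):
        swarm[slot].pbest_x = elite.x.copy()
        swarm[slot].pbest_obj = elite.objectives.copy()
    return ga_population, swarm


def _safe_evaluate(problem, x, archive, history):
    try:
        return problem.evaluate(x)
    except Exception as exc:  # checkpoint and surface a fallback
        fallback = archive.best_by_objective(0).x if len(archive) else x
        raise OptimizationAborted(
            f"objective evaluation failed: {exc}", archive, history, fallback
        ) from exc


def run_hybrid(
    problem,
    cfg: HybridConfig,
    ref_point: Optional[np.ndarray] = None,
) -> tuple[ParetoArchive, list[dict]]:
    """Run the hybrid optimizer; returns the final archive and a
    per-iteration history (hypervolume, diversity, rates).  Fully
    deterministic for a given ``cfg.rng_seed``."""
    seeds = np.random.SeedSequence(cfg.rng_seed).spawn(3)
    ga_rng = np.random.default_rng(seeds[0])
    pso_rng = np.random.default_rng(seeds[1])

    lo, hi = problem.bounds
    dim = len(lo)
    archive = ParetoArchive(capacity=cfg.archive_capacity)
    history: list[dict] = []

    pop = [
        Individual(x=lo + ga_rng.random(dim) * (hi - lo)) for _ in range(cfg.ga_pop_size)
    ]
    for ind in pop:
        ind.objectives = _safe_evaluate(problem, ind.x, archive, history)
    swarm = []
    for _ in range(cfg.swarm_size):
        x = lo + pso_rng.random(dim) * (hi - lo)
        obj = _safe_evaluate(problem, x, archive, history)
        swarm.append(Particle(x=x, v=np.zeros(dim), pbest_x=x.copy(), pbest_obj=obj, objectives=obj))

    archive.update(pop + [Individual(x=p.x, objectives=p.objectives) for p in swarm])
    if ref_point is None:
        ref_point = _init_reference([ind.objectives for ind in pop] + [p.objectives for p in swarm])
    ref_point = np.asarray(ref_point, dtype=float)

    rates = Rates(
        crossover_p=cfg.crossover_p,
        mutation_p=cfg.mutation_p,
        c1=cfg.c1,
        c2=cfg.c2,
        inertia_floor=cfg.inertia_end,
    )

    for it in range(cfg.max_iters):
        # --- GA generation
        _rank_population(pop)
        children: list[Individual] = []
        while len(children) < cfg.ga_pop_size:
            p1 = tournament_select(pop, cfg.tournament_k, ga_rng)
            p2 = tournament_select(pop, cfg.tournament_k, ga_rng)
            c1x, c2x = sbx_crossover(p1.x, p2.x, rates.crossover_p, cfg.eta_c, ga_rng, (lo, hi))
            for cx in (c1x, c2x):
                cx = polynomial_mutation(cx, rates.mutation_p, cfg.eta_m, ga_rng, (lo, hi))
                child = Individual(x=cx)
                child.objectives = _safe_evaluate(problem, cx, archive, history)
                children.append(child)
                if len(children) >= cfg.ga_pop_size:
                    break
        pop = environmental_selection(pop + children, cfg.ga_pop_size)

        # --- PSO sweep
        for particle in swarm:
            guide = archive.sample_guide(pso_rng).x
            pso_step(
                particle,
                guide,
                it,
                cfg.max_iters,
                rates.c1,
                rates.c2,
                pso_rng,
                (lo, hi),
                v_max_fraction=cfg.v_max_fraction,
                inertia_start=cfg.inertia_start,
                inertia_end=rates.inertia_floor
                if rates.inertia_floor > cfg.inertia_end
                else cfg.inertia_end,
            )
            particle.objectives = _safe_evaluate(problem, particle.x, archive, history)
            if particle.pbest_obj is None or dominates(particle.objectives, particle.pbest_obj):
                particle.pbest_x = particle.x.copy()
                particle.pbest_obj = particle.objectives.copy()
            elif not dominates(particle.pbest_obj, particle.objectives) and pso_rng.random() < 0.5:
                particle.pbest_x = particle.x.copy()
                particle.pbest_obj = particle.objectives.copy()

        archive.update(children + [Individual(x=p.x, objectives=p.objectives) for p in swarm])

        if cfg.migration_count and (it + 1) % cfg.migration_interval == 0:
            migrate(pop, swarm, archive, cfg.migration_count)

        hv = archive.hypervolume(ref_point)
        finite = [m.crowding for m in archive.members if math.isfinite(m.crowding or math.inf)]
        diversity = float(np.mean(finite)) if finite else math.inf
        history.append(
            {
                "iteration": it,
                "hypervolume": hv,
                "diversity": diversity,
                "crossover_p": rates.crossover_p,
                "mutation_p": rates.mutation_p,
                "c1": rates.c1,
                "c2": rates.c2,
            }
        )
        rates = adapt_rates(history, rates, cfg.adapt)

    return archive, history


def run_nsga2(
    problem,
    pop_size: int = 50,
    max_iters: int = 100,
    rng_seed: int = 0,
    crossover_p: float = 0.8,
    mutation_p: float = 0.02,
    eta_c: float = 15.0,
    eta_m: float = 20.0,
    tournament_k: int = 3,
    ref_point: Optional[np.ndarray] = None,
) -> tuple[list[Individual], list[dict]]:
    """Reference single-population NSGA-II under the same operator suite;
    returns the final nondominated front and a hypervolume history."""
    rng = np.random.default_rng(rng_seed)
    lo, hi = problem.bounds
    dim = len(lo)
    pop = [Individual(x=lo + rng.random(dim) * (hi - lo)) for _ in range(pop_size)]
    for ind in pop:
        ind.objectives = problem.evaluate(ind.x)
    if ref_point is None:
        ref_point = _init_reference([ind.objectives for ind in pop])
    ref_point = np.asarray(ref_point, dtype=float)
    history = []
    for it in range(max_iters):
        _rank_population(pop)
        children = []
        while len(children) < pop_size:
            p1 = tournament_select(pop, tournament_k, rng)
            p2 = tournament_select(pop, tournament_k, rng)
            c1x, c2x = sbx_crossover(p1.x, p2.x, crossover_p, eta_c, rng, (lo, hi))
            for cx in (c1x, c2x):
                cx = polynomial_mutation(cx, mutation_p, eta_m, rng, (lo, hi))
                children.append(Individual(x=cx, objectives=problem.evaluate(cx)))
                if len(children) >= pop_size:
                    break
        pop = environmental_selection(pop + children, pop_size)
        front = nondominated_sort(pop)[0]
        pts = [f.objectives for f in front if np.all(f.objectives < ref_point)]
        from .core import hypervolume as _hv

        history.append(
            {"iteration": it, "hypervolume": _hv(pts, ref_point) if pts else 0.0}
        )
    _rank_population(pop)
    return nondominated_sort(pop)[0], history


def _simplex_weights(n_obj: int, n_points: int) -> np.ndarray:
    """Das-Dennis style simplex lattice with at least n_points vectors."""
    h = 1
    while math.comb(h + n_obj - 1, n_obj - 1) < n_points:
        h += 1
    grid = []

    def rec(prefix, remaining, slots):
        if slots == 1:
            grid.append(prefix + [remaining])
            return
        for v in range(remaining + 1):
            rec(prefix + [v], remaining - v, slots - 1)

    rec([], h, n_obj)
    return np.asarray(grid, dtype=float) / h


def run_moead(
    problem,
    pop_size: int = 50,
    max_iters: int = 100,
    rng_seed: int = 0,
    neighborhood: int = 10,
    crossover_p: float = 0.9,
    mutation_p: float = 0.05,
    eta_c: float = 15.0,
    eta_m: float = 20.0,
) -> tuple[list[Individual], list[dict]]:
    """Tchebycheff-decomposition baseline (MOEA/D-style)."""
    rng = np.random.default_rng(rng_seed)
    lo, hi = problem.bounds
    dim = len(lo)
    W = _simplex_weights(problem.n_objectives, pop_size)[:pop_size]
    # neighbourhoods by weight-vector distance
    d = np.linalg.norm(W[:, None, :] - W[None, :, :], axis=2)
    B = np.argsort(d, axis=1)[:, :neighborhood]
    X = [lo + rng.random(dim) * (hi - lo) for _ in range(len(W))]
    F = [problem.evaluate(x) for x in X]
    z = np.min(np.stack(F), axis=0)

    def g(fv, w):
        return np.max(np.where(w > 0, w, 1e-6) * np.abs(fv - z))

    history = []
    for it in range(max_iters):
        for i in range(len(W)):
            a, b = rng.choice(B[i], size=2, replace=False)
            c1x, _ = sbx_crossover(X[a], X[b], crossover_p, eta_c, rng, (lo, hi))
            y = polynomial_mutation(c1x, mutation_p, eta_m, rng, (lo, hi))
            fy = problem.evaluate(y)
            z = np.minimum(z, fy)
            for j in B[i]:
                if g(fy, W[j]) <= g(F[j], W[j]):
                    X[j], F[j] = y, fy
        history.append({"iteration": it})
    pop = [Individual(x=x, objectives=f) for x, f in zip(X, F)]
    return nondominated_sort(pop)[0], history
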