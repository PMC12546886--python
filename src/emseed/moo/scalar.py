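"""Scalarizations and adaptive control: comprehensive weighted fitness,
Tchebycheff aggregation, the recursive parameter update, on-line rate
adaptation, and the convergence-iteration metric."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScalarFitnessConfig:
    weights: tuple
    f_min: tuple
    f_max: tuple

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if any(hi <= lo for lo, hi in zip(self.f_min, self.f_max)):
            raise ValueError("f_max must exceed f_min componentwise")


def scalar_fitness(objs: Sequence[float], cfg: ScalarFitnessConfig) -> float:
    """Sum of w_i (f_max - f_i)/(f_max - f_min); 1 at the ideal corner,
    0 at the worst.  Out-of-range objectives are clipped (logged)."""
    f = np.asarray(objs, dtype=float)
    lo = np.asarray(cfg.f_min, dtype=float)
    hi = np.asarray(cfg.f_max, dtype=float)
    if np.any(f < lo) or np.any(f > hi):
        log.debug("objective vector clipped into normalization bounds")
        f = np.clip(f, lo, hi)
    return float(np.dot(np.asarray(cfg.weights), (hi - f) / (hi - lo)))


@dataclass(frozen=True)
class WeightVector:
    lam: tuple
    z_star: tuple

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.lam):
            raise ValueError("lambda components must be non-negative")
        if abs(sum(self.lam) - 1.0) > 1e-9:
            raise ValueError("lambda must lie on the simplex")


def tchebycheff(objs: Sequence[float], wv: WeightVector) -> float:
    """max_i lambda_i |f_i - z*_i|."""
    f = np.asarray(objs, dtype=float)
    return float(np.max(np.asarray(wv.lam) * np.abs(f - np.asarray(wv.z_star))))


@dataclass(frozen=True)
class AdaptiveController:
    alpha: float = 0.7
    beta: float = 0.3
    window: int = 10

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def adaptive_update(
    x_t: np.ndarray,
    delta_opt: np.ndarray,
    delta_feedback: np.ndarray,
    ctrl: AdaptiveController,
    bounds: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """x_{t+1} = x_t + alpha dx_opt + beta dx_feedback, clipped to bounds."""
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != np.shape(delta_opt) or x_t.shape != np.shape(delta_feedback):
        raise ValueError("vector dimension mismatch")
    lo, hi = bounds
    return np.clip(x_t + ctrl.alpha * np.asarray(delta_opt) + ctrl.beta * np.asarray(delta_feedback), lo, hi)


@dataclass(frozen=True)
class Rates:
    crossover_p: float
    mutation_p: float
    c1: float
    c2: float
    inertia_floor: float = 0.4


@dataclass(frozen=True)
class AdaptRatesConfig:
    window: int = 10
    hv_stagnation_tol: float = 1e-9
    mutation_cap: float = 0.2
    crossover_floor: float = 0.6
    diversity_threshold: float = 0.05
    inertia_floor_cap: float = 0.6


def adapt_rates(history: Sequence[dict], rates: Rates, cfg: AdaptRatesConfig) -> Rates:
    """Rule-based on-line adaptation over a sliding history window.

    Hypervolume stagnation over a full window inflates the mutation rate
    (x1.5, capped) and raises the inertia floor; low archive diversity
    (mean crowding) lowers the crossover rate (floored).
    """
    if not history:
        raise ValueError("history window is empty")
    out = rates
    tail = list(history)[-cfg.window :]
    if len(tail) >= cfg.window:
        hv = [h["hypervolume"] for h in tail]
        if max(hv) - min(hv) < cfg.hv_stagnation_tol:
            new_m = min(out.mutation_p * 1.5, cfg.mutation_cap)
            new_floor = min(out.inertia_floor + 0.05, cfg.inertia_floor_cap)
            if new_m != out.mutation_p or new_floor != out.inertia_floor:
                log.debug("hv stagnation: mutation %.4f -> %.4f", out.mutation_p, new_m)
            out = replace(out, mutation_p=new_m, inertia_floor=new_floor)
    div = [h.get("diversity", math.inf) for h in tail]
    if np.mean(div) < cfg.diversity_threshold:
        new_c = max(out.crossover_p - 0.05, cfg.crossover_floor)
        if new_c != out.crossover_p:
            log.debug("low diversity: crossover %.3f -> %.3f", out.crossover_p, new_c)
        out = replace(out, crossover_p=new_c)
    return out


def convergence_iteration(history_hv: Sequence[float], tol: float, patience: int) -> float:
    """First iteration after which hypervolume changes stay below ``tol``
    for ``patience`` consecutive iterations; ``inf`` if that never happens."""
    if len(history_hv) == 0:
        raise ValueError("history is empty")
    diffs = np.abs(np.diff(np.asarray(history_hv, dtype=float)))
    if len(diffs) == 0:
        return 0.0
    below = diffs < tol
    run = 0
    for i, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run >= patience:
            return float(i - patience + 1)
    return math.inf
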