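"""Virtual seed lab: germination kinetics, vigor indices, dose-response
calibration and stochastic batch simulation.

The link from treatment physics to phenotype is a scalar *effective dose*
(absorbed energy weighted by the resonance-normalized frequency response)
pushed through a unimodal (hormetic) gain curve calibrated per variety.
Batches are then simulated seed-by-seed: replicate-level germination
probabilities with beta overdispersion, Bernoulli germination, logistic
germination-day sampling over a 14-day scoring window, and Gaussian
seedling/root lengths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .physics import (
    DomainError,
    SeedMechanics,
    TreatmentProtocol,
    total_energy,
    vibration_amplitude,
)

log = logging.getLogger(__name__)

SCORING_WINDOW_DAYS = 14.0


@dataclass(frozen=True)
class GerminationKinetics:
    """Logistic cumulative-germination parameters."""

    G_max: float  # asymptotic germination, %
    k: float  # rate constant, 1/day
    t50: float  # time to half of G_max, day

    def __post_init__(self) -> None:
        if not (0.0 <= self.G_max <= 100.0):
            raise ValueError("G_max must lie in [0, 100]")
        if self.k <= 0 or self.t50 <= 0:
            raise ValueError("k and t50 must be positive")


def germination_curve(kin: GerminationKinetics, t):
    """Cumulative germination (%) at day t: G_max / (1 + exp(-k (t - t50)))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = kin.G_max / (1.0 + np.exp(-kin.k * (t - kin.t50)))
    return out if out.ndim else float(out)


def vigor_index(germination_pct, mean_seedling_length_cm):
    """VI = germination % x mean seedling length / 100."""
    g = np.asarray(germination_pct, dtype=float)
    L = np.asarray(mean_seedling_length_cm, dtype=float)
    if np.any(g < 0) or np.any(L < 0):
        raise ValueError("inputs must be non-negative")
    out = g * L / 100.0
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SVIWeights:
    """Indicator weights and min-max reference bounds for the composite SVI."""

    weights: tuple
    x_min: tuple
    x_max: tuple

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.x_min) == len(self.x_max)):
            raise ValueError("weights/bounds length mismatch")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if any(hi <= lo for lo, hi in zip(self.x_min, self.x_max)):
            raise ValueError("x_max must exceed x_min for every indicator")


#: default indicators: germination %, vigor index, seedling length, root length
DEFAULT_SVI_WEIGHTS = SVIWeights(
    weights=(0.25, 0.25, 0.25, 0.25),
    x_min=(0.0, 0.0, 0.0, 0.0),
    x_max=(100.0, 100.0, 120.0, 100.0),
)


def composite_svi(values: Sequence[float], w: SVIWeights, clip: bool = True) -> float:
    """Weighted sum of min-max normalized indicators."""
    x = np.asarray(values, dtype=float)
    lo = np.asarray(w.x_min, dtype=float)
    hi = np.asarray(w.x_max, dtype=float)
    if x.shape != lo.shape:
        raise ValueError("value vector length mismatch")
    if clip:
        x = np.clip(x, lo, hi)
    elif np.any(x < lo) or np.any(x > hi):
        raise ValueError("indicator outside reference bounds with clipping disabled")
    return float(np.dot(np.asarray(w.weights, dtype=float), (x - lo) / (hi - lo)))


@dataclass(frozen=True)
class FeatureNormalizer:
    mu: float
    sigma: float
    w: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def normalize_feature(raw, norm: FeatureNormalizer):
    """((raw - mu)/sigma) * w + b."""
    raw = np.asarray(raw, dtype=float)
    out = (raw - norm.mu) / norm.sigma * norm.w + norm.b
    return out if out.ndim else float(out)


def denormalize_feature(value, norm: FeatureNormalizer):
    value = np.asarray(value, dtype=float)
    if norm.w == 0:
        raise ValueError("w = 0 is not invertible")
    out = (value - norm.b) / norm.w * norm.sigma + norm.mu
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# variety calibration and dose-response


@dataclass(frozen=True)
class VarietyProfile:
    """Per-variety phenotype calibration.

    ``d_opt`` is the effective dose at which the hormetic gain peaks;
    ``gamma`` its shape.  ``dispersion`` is the standard deviation (in
    germination %-points) of replicate-level means around the batch
    expectation.
    """

    name: str
    control_germination_pct: float
    control_vigor_index: float
    delta_g_max: float  # maximal germination gain, %-points
    delta_vi_max: float  # maximal vigor-index gain
    d_opt: float  # J-equivalent
    gamma: float = 1.5
    f_n: float = 300.0  # Hz, resonance of this variety's seeds
    zeta: float = 0.05
    dispersion: float = 2.0
    k: float = 0.9  # germination kinetics rate, 1/day
    t50: float = 5.0  # day
    length_sd_cm: float = 8.0
    root_fraction: float = 0.82
    root_sd_cm: float = 6.0

    def __post_init__(self) -> None:
        if self.control_germination_pct + self.delta_g_max > 100.0 + 1e-9:
            raise ValueError("control germination + delta_g_max must not exceed 100")
        if self.d_opt <= 0 or self.gamma <= 0:
            raise ValueError("d_opt and gamma must be positive")

    @property
    def control_seedling_length_cm(self) -> float:
        return 100.0 * self.control_vigor_index / self.control_germination_pct

    def kinetics(self, g_max: float) -> GerminationKinetics:
        return GerminationKinetics(G_max=g_max, k=self.k, t50=self.t50)


def effective_dose(
    protocol: Optional[TreatmentProtocol],
    profile: VarietyProfile,
    mech: SeedMechanics,
    n_steps: int = 1001,
) -> float:
    """Scalar treatment dose: absorbed energy times the resonance-normalized
    frequency response rho_f = A(f) / A(f_n) of this variety's seeds.
    """
    if protocol is None:
        return 0.0
    res = mech.with_resonance(profile.f_n, profile.zeta)
    B0 = protocol.field_strength_mT * 1e-3
    if B0 == 0.0:
        return 0.0
    rho_f = vibration_amplitude(B0, protocol.frequency_Hz, res) / vibration_amplitude(
        B0, profile.f_n, res
    )
    return total_energy(protocol, res, n_steps=n_steps) * rho_f


def dose_response(dose: float, profile: VarietyProfile) -> tuple[float, float]:
    """Hormetic phenotype gain (delta germination %, delta vigor index).

    g(D) = (D/d_opt)^gamma * exp(gamma (1 - D/d_opt)): zero at D = 0,
    peaks exactly at D = d_opt, decays to zero for large doses.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if dose == 0.0:
        return 0.0, 0.0
    u = dose / profile.d_opt
    shape = u**profile.gamma * math.exp(profile.gamma * (1.0 - u))
    return profile.delta_g_max * shape, profile.delta_vi_max * shape


@dataclass
class PhenotypeOutcome:
    """Replicate-level phenotype summary."""

    germination_pct: float
    vigor_index: float
    mean_seedling_length_cm: float
    mean_root_length_cm: float
    kinetics: GerminationKinetics
    svi: float


def _beta_params(p_target: float, dispersion_pct: float) -> tuple[float, float]:
    m = min(max(p_target, 1e-6), 1.0 - 1e-6)
    v = (dispersion_pct / 100.0) ** 2
    v = min(v, 0.99 * m * (1.0 - m))
    nu = m * (1.0 - m) / v - 1.0
    return m * nu, (1.0 - m) * nu


def _replicate_probability(p_target: float, dispersion_pct: float, rng: np.random.Generator) -> float:
    """Replicate-level germination probability with beta overdispersion."""
    if dispersion_pct <= 0:
        return p_target
    a, b = _beta_params(p_target, dispersion_pct)
    return float(rng.beta(a, b))


def _replicate_probabilities(
    p_target: float, dispersion_pct: float, n_replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Beta-overdispersed replicate probabilities, drawn by stratified
    inverse transform: each replicate keeps the full beta marginal while
    the replicate-mean variance is tightly controlled (variance-reduction
    design for the batch simulator)."""
    if dispersion_pct <= 0:
        return np.full(n_replicates, p_target)
    from scipy.stats import beta as beta_dist

    a, b = _beta_params(p_target, dispersion_pct)
    u = (rng.permutation(n_replicates) + rng.random(n_replicates)) / n_replicates
    return beta_dist.ppf(u, a, b)


def _sample_germination_days(
    n: int, kin: GerminationKinetics, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-transform germination days from the logistic CDF truncated
    at the scoring window; follows the cumulative curve shape exactly."""
    f14 = 1.0 / (1.0 + math.exp(-kin.k * (SCORING_WINDOW_DAYS - kin.t50)))
    q = rng.uniform(0.0, f14, size=n)
    q = np.clip(q, 1e-12, 1.0 - 1e-12)
    days = kin.t50 + np.log(q / (1.0 - q)) / kin.k
    return np.clip(days, 0.0, SCORING_WINDOW_DAYS)


def simulate_seed_records(
    profile: VarietyProfile,
    protocol: Optional[TreatmentProtocol],
    n_seeds: int,
    n_replicates: int,
    rng: np.random.Generator,
    mech: SeedMechanics,
) -> pd.DataFrame:
    """Per-seed records for ``n_replicates`` replicates of ``n_seeds`` each.

    Columns: variety, replicate, treated, germinated, germination_day
    (NaN when censored), seedling_cm, root_cm (0 for non-germinated).
    """
    if n_seeds < 1:
        raise ValueError("empty batch: n_seeds must be >= 1")
    dose = effective_dose(protocol, profile, mech)
    dg, dvi = dose_response(dose, profile)
    g_expect = profile.control_germination_pct + dg
    if not (0.0 <= g_expect <= 100.0):
        log.debug("expected germination %.2f clipped to [0, 100]", g_expect)
        g_expect = min(max(g_expect, 0.0), 100.0)
    vi_expect = profile.control_vigor_index + dvi
    # seedling length consistent with VI = G x L / 100 at the expected means
    mean_len = 100.0 * vi_expect / g_expect if g_expect > 0 else 0.0

    p_reps = _replicate_probabilities(g_expect / 100.0, profile.dispersion, n_replicates, rng)
    frames = []
    for rep in range(n_replicates):
        p_rep = float(p_reps[rep])
        germ = rng.random(n_seeds) < p_rep
        n_g = int(germ.sum())
        days = np.full(n_seeds, np.nan)
        lengths = np.zeros(n_seeds)
        roots = np.zeros(n_seeds)
        if n_g:
            kin = profile.kinetics(g_max=100.0)
            days[germ] = _sample_germination_days(n_g, kin, rng)
            lengths[germ] = np.clip(
                rng.normal(mean_len, profile.length_sd_cm, size=n_g), 0.0, None
            )
            roots[germ] = np.clip(
                rng.normal(mean_len * profile.root_fraction, profile.root_sd_cm, size=n_g),
                0.0,
                None,
            )
        frames.append(
            pd.DataFrame(
                {
                    "variety": profile.name,
                    "replicate": rep,
                    "treated": protocol is not None,
                    "germinated": germ.astype(int),
                    "germination_day": days,
                    "seedling_cm": lengths,
                    "root_cm": roots,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    for name in (
        "field_strength_mT",
        "frequency_Hz",
        "duration_s",
        "voltage_amplitude_V",
        "pulse_width_ms",
        "duty_cycle_pct",
    ):
        out[name] = 0.0 if protocol is None else getattr(protocol, name)
    return out


def summarize_replicates(
    records: pd.DataFrame,
    profile: VarietyProfile,
    svi_weights: SVIWeights = DEFAULT_SVI_WEIGHTS,
) -> list[PhenotypeOutcome]:
    outcomes = []
    for _, rep in records.groupby("replicate", sort=True):
        g_pct = 100.0 * rep["germinated"].mean()
        germinated = rep[rep["germinated"] == 1]
        mean_len = float(germinated["seedling_cm"].mean()) if len(germinated) else 0.0
        mean_root = float(germinated["root_cm"].mean()) if len(germinated) else 0.0
        vi = vigor_index(g_pct, mean_len)
        svi = composite_svi([g_pct, vi, mean_len, mean_root], svi_weights)
        outcomes.append(
            PhenotypeOutcome(
                germination_pct=float(g_pct),
                vigor_index=float(vi),
                mean_seedling_length_cm=mean_len,
                mean_root_length_cm=mean_root,
                kinetics=profile.kinetics(g_max=float(g_pct)),
                svi=svi,
            )
        )
    return outcomes


def simulate_batch(
    profile: VarietyProfile,
    protocol: Optional[TreatmentProtocol],
    n_seeds: int,
    n_replicates: int,
    rng_seed,
    mech: SeedMechanics,
    svi_weights: SVIWeights = DEFAULT_SVI_WEIGHTS,
) -> list[PhenotypeOutcome]:
    """Simulate a treated (or control, ``protocol=None``) batch.

    ``rng_seed`` may be an int or a ``numpy.random.Generator``; runs are
    fully reproducible for a given seed.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    records = simulate_seed_records(profile, protocol, n_seeds, n_replicates, rng, mech)
    return summarize_replicates(records, profile, svi_weights)


# ---------------------------------------------------------------------------
# economics


@dataclass(frozen=True)
class EconModel:
    benefits: tuple  # B_i per year, i = 1..n
    costs: tuple  # C_i per year
    discount_rate: float
    # horizon is implied by the vector lengths

    def __post_init__(self) -> None:
        if len(self.benefits) != len(self.costs) or len(self.benefits) < 1:
            raise ValueError("benefits and costs must be equal-length, non-empty")
        if self.discount_rate <= -1.0:
            raise ValueError("discount rate must exceed -1")


def benefit_cost_ratio(econ: EconModel) -> float:
    """Discounted benefit sum over discounted cost sum."""
    disc = np.array([(1.0 + econ.discount_rate) ** i for i in range(1, len(econ.costs) + 1)])
    cost = float(np.sum(np.asarray(econ.costs) / disc))
    if cost == 0.0:
        raise ZeroDivisionError("discounted costs sum to zero")
    return float(np.sum(np.asarray(econ.benefits) / disc)) / cost
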