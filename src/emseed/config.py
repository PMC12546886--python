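"""Configuration loading and validation.

A single YAML document configures physics constants, variety calibration,
optimizer settings and the surrogate network.  Shipped defaults live in
``defaults.yaml`` next to this module; a user file overrides any subset
(deep merge).  Validation is performed by pydantic models before any
domain object is built.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .phenotype import VarietyProfile, effective_dose
from .physics import CoilSpec, PowerModel, SeedMechanics, TreatmentProtocol


class CoilConfig(BaseModel):
    radius_m: float = Field(gt=0)
    separation_m: float = Field(gt=0)
    coil_resistance_ohm: float = Field(ge=0)
    n_turns: int = Field(ge=1, default=500)
    wire_diameter_mm: float = Field(gt=0, default=1.2)


class SeedMechanicsConfig(BaseModel):
    V_seed: float = Field(gt=0)
    rho_seed: float = Field(gt=0)
    f_n: float = Field(gt=0)
    zeta: float = Field(gt=0, lt=1)


class LossesConfig(BaseModel):
    switching_loss_W: float = Field(ge=0, default=0.0)
    control_power_W: float = Field(ge=0, default=0.0)


class PhysicsConfig(BaseModel):
    coil: CoilConfig
    seed_mechanics: SeedMechanicsConfig
    impedance_ohm: float = Field(gt=0, default=10.0)
    losses: LossesConfig = LossesConfig()


class ProtocolConfig(BaseModel):
    field_strength_mT: float
    frequency_Hz: float
    duration_s: float
    voltage_amplitude_V: float
    pulse_width_ms: float
    duty_cycle_pct: float


class VarietyConfig(BaseModel):
    name: str
    control_germination_pct: float = Field(ge=0, le=100)
    control_vigor_index: float = Field(ge=0)
    delta_g_max: float = Field(ge=0)
    delta_vi_max: float = Field(ge=0)
    gamma: float = Field(gt=0, default=1.5)
    f_n: float = Field(gt=0, default=300.0)
    zeta: float = Field(gt=0, lt=1, default=0.05)
    dispersion: float = Field(ge=0, default=2.0)
    k: float = Field(gt=0, default=0.9)
    t50: float = Field(gt=0, default=5.0)
    d_opt: Optional[float] = None
    reference_protocol: ProtocolConfig

    @field_validator("d_opt")
    @classmethod
    def _positive_if_given(cls, v):
        if v is not None and v <= 0:
            raise ValueError("d_opt must be positive")
        return v


class AdaptConfig(BaseModel):
    alpha: float = Field(ge=0, default=0.7)
    beta: float = Field(ge=0, default=0.3)
    window: int = Field(ge=1, default=10)
    hv_stagnation_tol: float = 1e-9
    mutation_cap: float = 0.2
    crossover_floor: float = 0.6
    diversity_threshold: float = 0.05


class OptimizerConfig(BaseModel):
    ga_pop_size: int = Field(ge=2, default=50)
    crossover_p: float = Field(ge=0, le=1, default=0.8)
    mutation_p: float = Field(ge=0, le=1, default=0.02)
    tournament_k: int = Field(ge=1, default=3)
    eta_c: float = 15.0
    eta_m: float = 20.0
    swarm_size: int = Field(ge=2, default=30)
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    v_max_fraction: float = 0.2
    migration_interval: int = Field(ge=1, default=10)
    migration_count: int = Field(ge=0, default=5)
    archive_capacity: int = Field(ge=2, default=200)
    max_iters: int = Field(ge=0, default=100)
    adapt: AdaptConfig = AdaptConfig()


class NetworkSettings(BaseModel):
    image_shape: tuple[int, int, int] = (64, 64, 3)
    sequence_shape: tuple[int, int] = (50, 128)
    conv_channels: tuple[int, int] = (32, 64)
    projection_channels: int = 8
    lstm_hidden: tuple[int, int] = (256, 128)
    fc_hidden: int = 512
    n_targets: int = 8
    attention_dk: int = 128


class TrainingSettings(BaseModel):
    lr_min: float = Field(gt=0, default=1e-4)
    lr_max: float = Field(gt=0, default=1e-2)
    cycle: int = Field(ge=1, default=200)
    max_epochs: int = Field(ge=1, default=10)
    clip_norm: float = Field(gt=0, default=1.0)
    batch_size: int = Field(ge=1, default=64)
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    lambda_reg: float = Field(ge=0, default=1e-4)

    @field_validator("split_fractions")
    @classmethod
    def _sums_to_one(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        return v


class RunConfig(BaseModel):
    physics: PhysicsConfig
    varieties: list[VarietyConfig]
    optimizer: OptimizerConfig = OptimizerConfig()
    network: NetworkSettings = NetworkSettings()
    training: TrainingSettings = TrainingSettings()


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load the shipped defaults, optionally deep-merged with a user file."""
    raw = yaml.safe_load(resources.files("emseed").joinpath("defaults.yaml").read_text())
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        raw = _deep_merge(raw, user)
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a validated configuration."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# materialization into domain objects


def build_coil(cfg: RunConfig) -> CoilSpec:
    c = cfg.physics.coil
    return CoilSpec(
        radius_m=c.radius_m,
        separation_m=c.separation_m,
        coil_resistance_ohm=c.coil_resistance_ohm,
        n_turns=c.n_turns,
        wire_diameter_mm=c.wire_diameter_mm,
    )


def build_mechanics(cfg: RunConfig) -> SeedMechanics:
    m = cfg.physics.seed_mechanics
    return SeedMechanics(V_seed=m.V_seed, rho_seed=m.rho_seed, f_n=m.f_n, zeta=m.zeta)


def build_losses(cfg: RunConfig) -> PowerModel:
    return PowerModel(
        switching_loss_W=cfg.physics.losses.switching_loss_W,
        control_power_W=cfg.physics.losses.control_power_W,
    )


def reference_protocol(vc: VarietyConfig) -> TreatmentProtocol:
    return TreatmentProtocol(**vc.reference_protocol.model_dump())


def build_varieties(cfg: RunConfig) -> list[VarietyProfile]:
    """Materialize variety profiles; a null ``d_opt`` is computed as the
    effective dose of the variety's reference protocol so that calibration
    and physics remain mutually consistent."""
    mech = build_mechanics(cfg)
    profiles = []
    for vc in cfg.varieties:
        base = VarietyProfile(
            name=vc.name,
            control_germination_pct=vc.control_germination_pct,
            control_vigor_index=vc.control_vigor_index,
            delta_g_max=vc.delta_g_max,
            delta_vi_max=vc.delta_vi_max,
            d_opt=vc.d_opt if vc.d_opt is not None else 1.0,  # placeholder
            gamma=vc.gamma,
            f_n=vc.f_n,
            zeta=vc.zeta,
            dispersion=vc.dispersion,
            k=vc.k,
            t50=vc.t50,
        )
        if vc.d_opt is None:
            d_opt = effective_dose(reference_protocol(vc), base, mech)
            base = VarietyProfile(
                name=base.name,
                control_germination_pct=base.control_germination_pct,
                control_vigor_index=base.control_vigor_index,
                delta_g_max=base.delta_g_max,
                delta_vi_max=base.delta_vi_max,
                d_opt=d_opt,
                gamma=base.gamma,
                f_n=base.f_n,
                zeta=base.zeta,
                dispersion=base.dispersion,
                k=base.k,
                t50=base.t50,
            )
        profiles.append(base)
    return profiles


def get_variety(cfg: RunConfig, name: str) -> VarietyProfile:
    for profile in build_varieties(cfg):
        if profile.name == name:
            return profile
    known = ", ".join(v.name for v in cfg.varieties)
    raise KeyError(f"unknown variety {name!r}; known varieties: {known}")
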