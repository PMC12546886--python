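"""Closed-form electromagnetic treatment physics.

Field in the treatment chamber, resonance-driven vibration amplitude of a
seed, energy deposited over a treatment, Helmholtz coil center field, and
the electrical power/energy budget of the driver.  All quantities are SI
internally; treatment protocols carry the operator-facing units (mT, Hz,
s, V, ms, %) and are converted on entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.integrate import simpson

MU_0 = 4.0e-7 * math.pi  # vacuum permeability (H/m)

#: closed [min, max] operating ranges of the six protocol variables
PROTOCOL_BOUNDS = {
    "field_strength_mT": (0.5, 5.0),
    "frequency_Hz": (10.0, 1000.0),
    "duration_s": (30.0, 300.0),
    "voltage_amplitude_V": (5.0, 50.0),
    "pulse_width_ms": (0.1, 10.0),
    "duty_cycle_pct": (10.0, 90.0),
}

PROTOCOL_FIELDS = tuple(PROTOCOL_BOUNDS)


def bounds_arrays() -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper bound vectors in the canonical protocol field order."""
    lo = np.array([PROTOCOL_BOUNDS[k][0] for k in PROTOCOL_FIELDS])
    hi = np.array([PROTOCOL_BOUNDS[k][1] for k in PROTOCOL_FIELDS])
    return lo, hi


class DomainError(ValueError):
    """Raised when a physics operation is called outside its domain."""


@dataclass(frozen=True)
class FieldConfig:
    """Oscillating, spatially attenuated magnetic field.

    B0 is stored in tesla; ``from_mT`` converts operator units.
    """

    B0: float  # peak flux density, T
    f: float  # Hz
    phi: float = 0.0  # rad
    alpha: float = 0.0  # spatial attenuation, 1/m

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.B0, self.f, self.phi, self.alpha)):
            raise DomainError("non-finite field configuration")
        if self.B0 < 0 or self.f < 0 or self.alpha < 0:
            raise DomainError("B0, f and alpha must be non-negative")

    @classmethod
    def from_mT(cls, B0_mT: float, f: float, phi: float = 0.0, alpha: float = 0.0) -> "FieldConfig":
        return cls(B0=B0_mT * 1e-3, f=f, phi=phi, alpha=alpha)

    @property
    def B0_mT(self) -> float:
        return self.B0 * 1e3


@dataclass(frozen=True)
class TreatmentProtocol:
    """The six operator-facing treatment variables."""

    field_strength_mT: float
    frequency_Hz: float
    duration_s: float
    voltage_amplitude_V: float
    pulse_width_ms: float
    duty_cycle_pct: float

    def __post_init__(self) -> None:
        for name, (lo, hi) in PROTOCOL_BOUNDS.items():
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"{name} is not finite")
            if not (lo <= v <= hi):
                raise DomainError(f"{name}={v} outside [{lo}, {hi}]")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PROTOCOL_FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "TreatmentProtocol":
        return cls(**dict(zip(PROTOCOL_FIELDS, map(float, x))))

    @property
    def duty_fraction(self) -> float:
        return self.duty_cycle_pct / 100.0

    def field_config(self, phi: float = 0.0, alpha: float = 0.0) -> FieldConfig:
        return FieldConfig.from_mT(self.field_strength_mT, self.frequency_Hz, phi, alpha)


@dataclass(frozen=True)
class SeedMechanics:
    """Mechanical constants of a seed treated as a damped oscillator."""

    V_seed: float  # m^3
    rho_seed: float  # kg/m^3
    f_n: float  # natural frequency, Hz
    zeta: float  # damping ratio
    eta: Optional[Callable[[np.ndarray], np.ndarray]] = None  # absorption efficiency

    def __post_init__(self) -> None:
        if self.V_seed <= 0 or self.rho_seed <= 0 or self.f_n <= 0:
            raise DomainError("V_seed, rho_seed and f_n must be positive")
        if not (0.0 < self.zeta < 1.0):
            raise DomainError("zeta must lie in (0, 1)")

    def efficiency(self, t: np.ndarray) -> np.ndarray:
        if self.eta is None:
            return np.ones_like(np.asarray(t, dtype=float))
        out = np.asarray(self.eta(np.asarray(t, dtype=float)), dtype=float)
        if np.any(out < -1e-12) or np.any(out > 1 + 1e-12):
            raise DomainError("eta(t) must stay in [0, 1]")
        return np.clip(out, 0.0, 1.0)

    def with_resonance(self, f_n: float, zeta: float) -> "SeedMechanics":
        return replace(self, f_n=f_n, zeta=zeta)


def saturating_efficiency(tau: float) -> Callable[[np.ndarray], np.ndarray]:
    """eta(t) = 1 - exp(-t/tau): absorption ramping up to unity."""
    if tau <= 0:
        raise DomainError("tau must be positive")
    return lambda t: 1.0 - np.exp(-np.asarray(t, dtype=float) / tau)


@dataclass(frozen=True)
class CoilSpec:
    radius_m: float
    separation_m: float
    coil_resistance_ohm: float
    n_turns: int = 500
    wire_diameter_mm: float = 1.2

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise DomainError("coil radius must be positive")
        if self.n_turns < 1:
            raise DomainError("n_turns must be >= 1")


@dataclass(frozen=True)
class PowerModel:
    switching_loss_W: float = 0.0
    control_power_W: float = 0.0

    def __post_init__(self) -> None:
        if self.switching_loss_W < 0 or self.control_power_W < 0:
            raise DomainError("losses must be non-negative")


# ---------------------------------------------------------------------------
# operations


def field_at(cfg: FieldConfig, r, t):
    """Flux density B0*cos(2*pi*f*t + phi)*exp(-alpha*r) at distance r, time t."""
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(r)) or np.any(~np.isfinite(t)):
        raise DomainError("r and t must be finite")
    if np.any(r < 0) or np.any(t < 0):
        raise DomainError("r and t must be non-negative")
    out = cfg.B0 * np.cos(2.0 * math.pi * cfg.f * t + cfg.phi) * np.exp(-cfg.alpha * r)
    return out if out.ndim else float(out)


def vibration_amplitude(B, f, mech: SeedMechanics):
    """Resonant vibration amplitude of the seed under flux density B at drive f.

    (B^2 V)/(2 mu0 rho) / sqrt((f_n^2 - f^2)^2 + (2 zeta f_n f)^2).
    """
    B = np.asarray(B, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise DomainError("f must be non-negative")
    denom = np.sqrt((mech.f_n**2 - f**2) ** 2 + (2.0 * mech.zeta * mech.f_n * f) ** 2)
    if np.any(denom == 0):
        raise DomainError("degenerate resonance: f_n and f both zero")
    out = (B**2 * mech.V_seed) / (2.0 * MU_0 * mech.rho_seed) / denom
    return out if out.ndim else float(out)


def resonance_peak_frequency(mech: SeedMechanics) -> float:
    """Drive frequency maximizing the amplitude, f_n*sqrt(1-2 zeta^2)."""
    if mech.zeta >= 1.0 / math.sqrt(2.0):
        return 0.0
    return mech.f_n * math.sqrt(1.0 - 2.0 * mech.zeta**2)


def total_energy(
    protocol: TreatmentProtocol,
    mech: SeedMechanics,
    n_steps: int = 1001,
    phi: float = 0.0,
    duty_mode: str = "average",
) -> float:
    """Energy absorbed over the treatment: Simpson quadrature of
    B(t)^2 V /(2 mu0) * eta(t) on [0, T] at chamber center (r = 0).

    The pulse train (pulse width / duty cycle) switches the field on and
    off with a millisecond period, orders of magnitude below the treatment
    duration.  ``duty_mode='average'`` (default) applies the on-fraction as
    a multiplier — exact in that fast-switching limit and smooth for the
    quadrature.  ``duty_mode='explicit'`` gates the integrand pointwise
    with period pulse_width/duty; the caller must supply n_steps fine
    enough to resolve the gate.
    """
    if protocol.duration_s <= 0:
        raise DomainError("duration must be positive")
    if n_steps < 2:
        raise DomainError("n_steps must be >= 2")
    T = protocol.duration_s
    t = np.linspace(0.0, T, int(n_steps))
    f = protocol.frequency_Hz
    B0 = protocol.field_strength_mT * 1e-3
    scale = mech.V_seed / (2.0 * MU_0)

    if duty_mode == "explicit":
        # pointwise pulse gating; caller must resolve both the field
        # oscillation and the millisecond gate with n_steps
        cfg = protocol.field_config(phi=phi)
        B = field_at(cfg, 0.0, t)
        width = protocol.pulse_width_ms * 1e-3
        period = width / protocol.duty_fraction
        integrand = B**2 * scale * mech.efficiency(t) * ((t % period) < width)
        return float(simpson(integrand, x=t))
    if duty_mode != "average":
        raise ValueError(f"unknown duty_mode {duty_mode!r}")

    # cos^2(2 pi f t + phi) = 1/2 + cos(4 pi f t + 2 phi)/2: integrate the
    # smooth half by Simpson and the oscillatory half exactly, so the result
    # does not alias however coarse the grid is relative to f.
    eta = mech.efficiency(t)
    s_mean = float(simpson(B0**2 * 0.5 * eta, x=t))
    if mech.eta is None:
        if f == 0.0:
            s_osc = B0**2 * 0.5 * math.cos(2.0 * phi) * T
        else:
            s_osc = (
                B0**2
                * (math.sin(4.0 * math.pi * f * T + 2.0 * phi) - math.sin(2.0 * phi))
                / (8.0 * math.pi * f)
            )
    else:
        # time-varying absorption: quadrature of the oscillatory half on a
        # grid fine enough for frequency 2f (bounded for tractability)
        n_osc = max(int(n_steps), min(int(32 * f * T) + 1, 2_000_001))
        t_osc = np.linspace(0.0, T, n_osc)
        s_osc = float(
            simpson(
                B0**2
                * 0.5
                * np.cos(4.0 * math.pi * f * t_osc + 2.0 * phi)
                * mech.efficiency(t_osc),
                x=t_osc,
            )
        )
    return float(protocol.duty_fraction * scale * (s_mean + s_osc))


def helmholtz_center_field(coil: CoilSpec, current: float, textbook_mode: bool = False) -> float:
    """Center flux density of the coil pair: mu0*N*I*R^2/(R^2+(z/2)^2)^(3/2) x 2.

    The default keeps the x2 convention of the source model; textbook_mode
    applies the conventional 1/2 per-coil Biot-Savart factor instead
    (i.e. drops the doubling).
    """
    if not math.isfinite(current):
        raise DomainError("current must be finite")
    base = MU_0 * coil.n_turns * current * coil.radius_m**2
    base /= (coil.radius_m**2 + (coil.separation_m / 2.0) ** 2) ** 1.5
    return base if textbook_mode else 2.0 * base


def electrical_power(current_rms: float, coil: CoilSpec, losses: PowerModel) -> float:
    """I^2 R_coil + switching + control losses (W)."""
    if current_rms < 0:
        raise DomainError("current_rms must be non-negative")
    return current_rms**2 * coil.coil_resistance_ohm + losses.switching_loss_W + losses.control_power_W


def protocol_energy_cost(
    protocol: TreatmentProtocol,
    coil: CoilSpec,
    losses: PowerModel,
    impedance_ohm: float = 10.0,
) -> float:
    """Electrical energy of one treatment run (J): P_total x duration.

    Drive current is a configured linear map of voltage amplitude,
    I = V / Z.
    """
    if impedance_ohm <= 0:
        raise DomainError("impedance must be positive")
    current = protocol.voltage_amplitude_V / impedance_ohm
    return electrical_power(current, coil, losses) * protocol.duration_s
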