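"""The calibrated seed-treatment optimization problem.

Decision vector: the six treatment variables in their operating ranges.
Objectives (all minimized): negative germination gain at the protocol's
effective dose, electrical energy of the run, and processing time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..phenotype import VarietyProfile, dose_response, effective_dose
from ..physics import (
    CoilSpec,
    PowerModel,
    SeedMechanics,
    TreatmentProtocol,
    bounds_arrays,
    protocol_energy_cost,
)


class ConstraintViolationError(ValueError):
    """Decision vector outside the box bounds."""


@dataclass
class SeedTreatmentProblem:
    profile: VarietyProfile
    mech: SeedMechanics
    coil: CoilSpec
    losses: PowerModel
    impedance_ohm: float = 10.0

    n_objectives: int = 3

    def __post_init__(self) -> None:
        self.lower, self.upper = bounds_arrays()

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.lower, self.upper

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < self.lower - 1e-9) or np.any(x > self.upper + 1e-9):
            raise ConstraintViolationError(f"decision vector {x} outside bounds")
        protocol = TreatmentProtocol.from_vector(np.clip(x, self.lower, self.upper))
        dose = effective_dose(protocol, self.profile, self.mech)
        dg, _ = dose_response(dose, self.profile)
        energy = protocol_energy_cost(protocol, self.coil, self.losses, self.impedance_ohm)
        return np.array([-dg, energy, protocol.duration_s])

    def dose_of(self, x: np.ndarray) -> float:
        protocol = TreatmentProtocol.from_vector(np.clip(x, self.lower, self.upper))
        return effective_dose(protocol, self.profile, self.mech)
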