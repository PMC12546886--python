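import numpy as np
import pytest

from emseed import config as cfgmod
from emseed.physics import (
    CoilSpec,
    PowerModel,
    SeedMechanics,
    TreatmentProtocol,
    bounds_arrays,
)


@pytest.fixture(scope="session")
def run_config():
    return cfgmod.load_config()


@pytest.fixture(scope="session")
def profiles(run_config):
    return cfgmod.build_varieties(run_config)


@pytest.fixture(scope="session")
def mech(run_config):
    return cfgmod.build_mechanics(run_config)


@pytest.fixture(scope="session")
def coil(run_config):
    return cfgmod.build_coil(run_config)


@pytest.fixture(scope="session")
def losses(run_config):
    return cfgmod.build_losses(run_config)


@pytest.fixture(scope="session")
def bounds():
    return bounds_arrays()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mid_protocol():
    return TreatmentProtocol(
        field_strength_mT=2.5,
        frequency_Hz=300.0,
        duration_s=120.0,
        voltage_amplitude_V=25.0,
        pulse_width_ms=5.0,
        duty_cycle_pct=50.0,
    )


@pytest.fixture
def simple_mech():
    return SeedMechanics(V_seed=1e-6, rho_seed=1000.0, f_n=100.0, zeta=0.1)
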