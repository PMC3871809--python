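"""Shared fixtures: parameter sets, environments, and season-long runs.

Full-season trajectories are expensive (a few seconds each), so the default
low- and high-crop runs are computed once per session and shared by every
test that inspects them.
"""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from kiwisim.environment import EnvironmentConfig, SyntheticEnvironment, TabulatedEnvironment

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from kiwisim.params import load_parameters
from kiwisim.simulator import SimulationConfig, simulate


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def env_config():
    return EnvironmentConfig()


@pytest.fixture(scope="session")
def synthetic_env(env_config):
    return SyntheticEnvironment(env_config)


@pytest.fixture(scope="session")
def low_traj():
    """Default full-season low crop-load run (half-hour RK4 step)."""
    return simulate(SimulationConfig(scenario="low"))


@pytest.fixture(scope="session")
def high_traj():
    """Full-season run with the phloem concentration lowered by 0.01 g/g."""
    return simulate(SimulationConfig(scenario="high"))


@pytest.fixture()
def constant_env():
    """Environment frozen at benign values; no transpiration gradient."""
    frame = pd.DataFrame({
        "t": [0.0, 400.0],
        "T": [20.0, 20.0],
        "H_a": [0.996, 0.996],   # equals the internal humidity: T_f = 0
        "Tr": [0.0, 0.0],
        "psi_x": [-1.0, -1.0],
        "C_p": [0.13, 0.13],
    })
    return TabulatedEnvironment(frame)
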