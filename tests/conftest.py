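"""Shared fixtures: solved control laws are expensive, so the common
configurations are solved once per session."""
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from visreach.task import make_experiment, NoiseSpec
from visreach.solver import solve

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def classical_noise(omega_w=1e-4):
    """Additive-only noise (no signal-, state-dependent or internal noise).

    omega_w is kept well-conditioned so that independently coded Kalman
    recursions agree to tight tolerance.
    """
    return NoiseSpec(sigma_f=0.0, sigma_g=np.zeros(6), a=0.0,
                     omega_eta=np.zeros(10), omega_w=np.full(6, omega_w))


@pytest.fixture(scope="session")
def exp1_config():
    """Default Experiment-1 configuration (12 starts, kappa=1, theta=0)."""
    return make_experiment("exp1")


@pytest.fixture(scope="session")
def cfg_orth(exp1_config):
    """Movement orthogonal to the visibility direction (start at 270 deg)."""
    return exp1_config.single(9)


@pytest.fixture(scope="session")
def cfg_opp(exp1_config):
    """Movement opposite to the visibility direction (start at 0 deg)."""
    return exp1_config.single(0)


@pytest.fixture(scope="session")
def cfg_classical(cfg_orth):
    return replace(cfg_orth, noise=classical_noise())


@pytest.fixture(scope="session")
def law_orth(cfg_orth):
    return solve(cfg_orth)


@pytest.fixture(scope="session")
def law_opp(cfg_opp):
    return solve(cfg_opp)


@pytest.fixture(scope="session")
def law_classical(cfg_classical):
    return solve(cfg_classical)
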