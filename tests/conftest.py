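from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wienerdm as w

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def defaults() -> w.DMParameters:
    """The start-up parameter set: a=1, z=0.5, nu=0.2, t0=300 ms, s2=1."""
    return w.DMParameters()


@pytest.fixture(scope="session")
def default_numerics() -> w.NumericsConfig:
    return w.NumericsConfig()


def long_curve(params: w.DMParameters, step_ms: float = 0.5) -> w.DensityCurve:
    """Density curve on a grid long and fine enough for accurate moments."""
    t_max = w.suggested_t_max_ms(params)
    n = int(math.ceil(t_max / step_ms)) + 1
    return w.density_curve(params, w.NumericsConfig(t_max_ms=t_max, n_points=n))


@pytest.fixture(scope="session")
def default_sample_200k(defaults) -> w.TrialSample:
    """One large simulated sample at the default set, shared across tests."""
    return w.simulate_trials(defaults, n=200_000, dt_s=1e-4, seed=20_260_101)


def conditional_mc_se(rts: np.ndarray) -> float:
    """Monte-Carlo standard error of a conditional RT mean."""
    return float(rts.std(ddof=1) / math.sqrt(len(rts)))
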