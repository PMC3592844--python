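import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import beeflight as bf

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    return bf.default_model()


@pytest.fixture(scope="session")
def default_sim(default_model):
    """A mid-sized simulation of the default model shared across tests."""
    return bf.simulate(default_model, 200_000, seed=77)


@pytest.fixture(scope="session")
def default_kinematics(default_sim):
    return default_sim.kinematics


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def ou_series(
    n=400_000, mu=0.4, sigma=0.05, gamma=2.0, dt=0.02, seed=2
) -> bf.KinematicSeries:
    """Exact-discretization Ornstein-Uhlenbeck speed process, angle frozen."""
    a = np.exp(-gamma * dt)
    gen = np.random.default_rng(seed)
    v = np.empty(n)
    v[0] = mu
    noise = sigma * np.sqrt(1 - a * a) * gen.standard_normal(n - 1)
    for i in range(n - 1):
        v[i + 1] = mu + a * (v[i] - mu) + noise[i]
    assert v.min() > 0, "choose OU parameters that keep speeds positive"
    return bf.KinematicSeries(dt=dt, v=v, theta=np.zeros(n), phi=np.zeros(n - 1))
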