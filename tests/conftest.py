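import numpy as np
import pytest

from pbcurves import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def spec1_world():
    """One realized spec1 map on a 100k-cell synthetic field, shared by
    the simulation-backed tests (resampling draws vary per test)."""
    env = sim.synthetic_field(100_000, seed=1)
    model = sim.load_species("spec1")
    surface = sim.probability_surface(model, env)
    real = sim.realize(surface, seed=2)
    return env, surface, real
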