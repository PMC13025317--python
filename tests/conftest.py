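import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from betadisp import GridSpec, ModelParams

settings.register_profile(
    "betadisp",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("betadisp")


@pytest.fixture
def small_grid() -> GridSpec:
    """A 10x6 grid: large enough for nontrivial dynamics, cheap to step."""
    return GridSpec(nx=10, ny=6)


@pytest.fixture
def reference_grid() -> GridSpec:
    """The reference 50x20 simulation domain."""
    return GridSpec(nx=50, ny=20)


@pytest.fixture
def quiet_params() -> ModelParams:
    """Unforced, unscreened, un-normalized dynamics (pure diffusion)."""
    return ModelParams(kappa=0.0, amplitude=0.0, dt=0.05, normalization="none")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
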