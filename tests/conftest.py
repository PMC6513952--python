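import numpy as np
import pytest

from chromstate.engine import SimulationConfig, run


class StubRng:
    """Deterministic RNG stub feeding scripted uniforms / integers."""

    def __init__(self, uniforms=(), integers=()):
        self._uniforms = list(uniforms)
        self._integers = list(integers)

    def random(self, size=None):
        if size is None:
            return self._uniforms.pop(0)
        return np.array([self._uniforms.pop(0) for _ in range(size)])

    def integers(self, *args):
        return self._integers.pop(0)


@pytest.fixture
def stub_rng_factory():
    return StubRng


@pytest.fixture(scope="session")
def warm_kernel():
    """Compile the numba kernel once up front so timing of later tests is flat."""
    run(SimulationConfig(duration=1.0, seed=0))


@pytest.fixture(scope="session")
def short_run(warm_kernel):
    """A short default-parameter run shared by read-only tests."""
    return run(SimulationConfig(duration=2000.0, seed=7))
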