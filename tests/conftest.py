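import numpy as np
import pytest

from pegsim import breathing_protocol, make_sensor, run_simulation


@pytest.fixture(scope="session")
def human_array():
    """Factory for the human-experiment layout: 3x A(0.01 M) + 3x U."""

    def build(params=None):
        kw = {"params": params} if params is not None else {}
        return [make_sensor("A", 0.01, **kw) for _ in range(3)] + [
            make_sensor("U", 0.0, **kw) for _ in range(3)
        ]

    return build


@pytest.fixture(scope="session")
def breathing_recording_5ppm(human_array):
    """Noise-free 15-min breathing run at 5 ppm NH3 (reused read-only)."""
    return run_simulation(human_array(), breathing_protocol(5.0, 15.0))


@pytest.fixture(scope="session")
def breathing_recording_clean(human_array):
    """Noise-free 15-min clean-breath (0 ppm) run (reused read-only)."""
    return run_simulation(human_array(), breathing_protocol(0.0, 15.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
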