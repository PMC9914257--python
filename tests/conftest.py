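import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20230203)


@pytest.fixture(scope="session")
def fast_spec():
    """A short, small-canvas simulation for quick image tests."""
    from dryshrink.synthetic import SimulationSpec

    return SimulationSpec(
        duration_min=2.0,
        canvas_height=130,
        canvas_width=180,
        disk_centers=((35, 35), (35, 90), (35, 145), (95, 35), (95, 90), (95, 145)),
        initial_radius_px=20.0,
        seed=7,
    )
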