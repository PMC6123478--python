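import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_cluster(rng):
    """A generic 50-point 3D cluster with anisotropic spread."""
    return rng.normal(size=(50, 3)) * np.array([40.0, 25.0, 10.0]) + np.array(
        [500.0, -200.0, 30.0]
    )


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()
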