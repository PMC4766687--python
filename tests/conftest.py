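import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import ctmigration as cm

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def spec():
    return cm.PhantomSpec()


def random_rotation(rng, max_deg=180.0):
    return cm.rotation_from_euler(rng.uniform(-max_deg, max_deg, 3))


def random_rigid(rng, max_deg=45.0, max_t=50.0):
    return cm.RigidTransform(
        random_rotation(rng, max_deg), rng.uniform(-max_t, max_t, 3)
    )


@pytest.fixture
def noncoplanar_set(rng):
    pts = rng.normal(0.0, 30.0, size=(9, 3))
    return cm.LandmarkSet(tuple(f"b{i}" for i in range(9)), pts, "bone")
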