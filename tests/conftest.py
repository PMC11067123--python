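import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from pdmotion import SimConfig, simulate_task_trajectories, build_channel_set

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ftn_traj():
    """Asymptomatic finger-to-nose performance, default study conditions."""
    return simulate_task_trajectories(SimConfig(seed=7))


@pytest.fixture(scope="session")
def hps_traj():
    return simulate_task_trajectories(SimConfig(task="HPS", seed=7))


@pytest.fixture(scope="session")
def ftn_channels(ftn_traj):
    return build_channel_set(ftn_traj)


@pytest.fixture(scope="session")
def hps_channels(hps_traj):
    return build_channel_set(hps_traj)


@pytest.fixture(scope="session")
def short_ftn_traj():
    """A 3-second performance, cheap enough for repeated transforms."""
    return simulate_task_trajectories(SimConfig(duration_s=3.0, seed=11))


def random_rotation(rng):
    """Uniform random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
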