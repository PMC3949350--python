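import numpy as np
import pytest

import behaviorcp as bcp


@pytest.fixture(scope="session")
def task():
    return bcp.TaskConfig()


@pytest.fixture(scope="session")
def quiet_params():
    """Clean logistic observer: no latent drift, no history, no coupling."""
    return bcp.GenerativeParams(
        latent_noise_sd=0.0, history_reward_weight=0.0, traj_coupling_gain=0.0,
        premature_rate_base=0.0,
    )


@pytest.fixture(scope="session")
def small_session(task):
    trials, trajs = bcp.simulate_session(
        task, bcp.GenerativeParams(), 300, seed=42
    )
    return trials, trajs


@pytest.fixture(scope="session")
def triangle_stack():
    """Rendered frame stack following a triangle-wave path (no noise).

    A ping-pong sweep keeps per-pixel blob occupancy below 50%, so the
    median background is exactly the rendered scene.
    """
    t = np.arange(120)
    tri = np.abs((t / 60.0) % 2 - 1)
    x = 40 + 100 * (1 - tri)
    y = 60 + 10 * np.sin(2 * np.pi * t / 40)
    path = np.column_stack([x, y])
    stack = bcp.render_synthetic_frames(path, image_size=(120, 160), noise_sd=0.0)
    return stack, path
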