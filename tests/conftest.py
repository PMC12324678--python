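import numpy as np
import pytest

from metanav import agent as ag


@pytest.fixture(scope="session")
def open_field_task():
    return ag.TaskConfig(conditions=("both",), kinds=("open",))


@pytest.fixture(scope="session")
def desk_trained(open_field_task):
    """Desk-scale trained agent, shared across the whole session.

    Trained once on the open-field 'both' condition at the desk-scale
    configuration (8 environments x 256-step rollouts x 300 updates).
    """
    params, curve = ag.train(
        open_field_task, ag.NetworkConfig(), ag.PPOConfig(), seed=1
    )
    return params, curve


@pytest.fixture(scope="session")
def tiny_trained(open_field_task):
    """A barely-trained agent for structural (non-performance) checks."""
    params, curve = ag.train(
        open_field_task,
        ag.NetworkConfig(),
        ag.PPOConfig(n_envs=2, rollout_steps=64, n_updates=3),
        seed=0,
    )
    return params, curve


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
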