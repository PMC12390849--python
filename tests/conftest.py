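import numpy as np
import pytest

from tinyrnn.cognitive import CognitiveAgent, make_model
from tinyrnn.task_envs import two_stage_miller, reversal_bartolo, simulate_task


@pytest.fixture(scope="session")
def miller_config():
    return two_stage_miller()


@pytest.fixture(scope="session")
def reversal_config():
    return reversal_bartolo()


@pytest.fixture(scope="session")
def mf1_two_stage_data(miller_config):
    """2,000 two-stage trials simulated from an mf1 agent."""
    agent = CognitiveAgent(make_model("mf1"), {"alpha": 0.5, "beta": 3.0})
    return simulate_task(miller_config, agent, 2000, seed=11)


@pytest.fixture(scope="session")
def masked_data(mf1_two_stage_data):
    """Copy of the two-stage data with a sprinkle of masked-out trials."""
    import copy
    data = copy.deepcopy(mf1_two_stage_data)
    rng = np.random.default_rng(0)
    sess = data.sessions[0]
    drop = rng.choice(sess.n_trials, size=100, replace=False)
    sess.mask[drop] = False
    sess.action[drop] = -1
    sess.state[drop] = -1
    return data


def random_params(model, rng):
    """Draw a plausible random parameter set for a cognitive model."""
    draw = {
        "unit": lambda: rng.uniform(0.05, 0.95),
        "unit_half": lambda: rng.uniform(0.55, 0.95),
        "pos": lambda: rng.uniform(0.2, 4.0),
        "real": lambda: rng.normal(0.0, 1.0),
    }
    return {name: float(draw[kind]()) for name, kind in model.PARAMS.items()}
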