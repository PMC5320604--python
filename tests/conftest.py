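import numpy as np
import pytest

from adaptpe import ModelParams, generate_experiment, simulate_agent


@pytest.fixture(scope="session")
def default_design():
    """One full default experiment design (186 trials, seed fixed)."""
    return generate_experiment(seed=11)


@pytest.fixture(scope="session")
def ph2_agent(default_design):
    """An agent simulated from known adaptive Pearce-Hall parameters."""
    params = ModelParams(model_id="PH2", k1=0.6, gamma=0.3, nu=0.7, sigma=3.0)
    trials = simulate_agent(params, default_design,
                            np.random.default_rng(101))
    return params, trials


@pytest.fixture(scope="session")
def rw1_agent(default_design):
    params = ModelParams(model_id="RW1", k=0.5, sigma=3.0)
    trials = simulate_agent(params, default_design,
                            np.random.default_rng(202))
    return params, trials
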