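import numpy as np
import pytest

from stepwise_bf.config import AgentConfig, NeuronConfig, TaskConfig
from stepwise_bf.synthetic import AgentPlan, simulate_session, simulate_study


@pytest.fixture(scope="session")
def task():
    return TaskConfig()


def small_agent(**kw):
    """Scaled-down agent for fast tests: fixed landmarks, ~90-trial sessions."""
    base = dict(
        n_sessions=6, d1_index=1, d1_jitter=0,
        d2_gap_choices=(2,), d2_gap_probs=(1.0,),
        transition_trial=25, transition_jitter=5,
        n_trials_mean=90.0, n_trials_sd=5.0, n_trials_min=60,
    )
    base.update(kw)
    return AgentConfig(**base)


@pytest.fixture(scope="session")
def agent_small():
    return small_agent()


@pytest.fixture(scope="session")
def neurons_small():
    return NeuronConfig(n_units=8)


@pytest.fixture(scope="session")
def d1_session(task, agent_small):
    """One simulated D1 session (events + latent truth), behavior only."""
    rng = np.random.default_rng(42)
    plan = AgentPlan.sample(agent_small, rng)
    events, truth = simulate_session(task, agent_small, plan.d1, rng, plan=plan)
    return events, truth, plan


@pytest.fixture(scope="session")
def small_study(task, agent_small, neurons_small):
    """Three simulated animals with spikes, scaled for speed."""
    return simulate_study(task, agent_small, neurons_small, n_animals=3, seed=7)
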