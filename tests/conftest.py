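import numpy as np
import pytest

from twostep.agents import make_agent
from twostep.simulate import Session, run_batch
from twostep.task_env import TaskConfig


@pytest.fixture(scope="session")
def q1_reduced_batch():
    """Q(1) agent (alpha=0.334, T=3.22) on the reduced blocks task."""
    agent = make_agent("q1", alpha=0.334, T=3.22)
    return run_batch(agent, TaskConfig.reduced(), 10, 10000, seed=1001)


@pytest.fixture(scope="session")
def mb_reduced_batch():
    """Model-based reference agent (alpha=0.5, T=5) on the reduced task."""
    agent = make_agent("model_based", alpha=0.5, T=5.0)
    return run_batch(agent, TaskConfig.reduced(), 10, 10000, seed=1002)


def make_session(choice1, common, second_state, outcome, choice2=None,
                 reward_probs=None, p_choice_a=None, meta=None) -> Session:
    """Hand-build a Session from event lists (test helper)."""
    n = len(choice1)
    choice1 = np.asarray(choice1, dtype=np.int64)
    common = np.asarray(common, dtype=np.int64)
    second_state = np.asarray(second_state, dtype=np.int64)
    outcome = np.asarray(outcome, dtype=np.int64)
    choice2 = (np.zeros(n, dtype=np.int64) if choice2 is None
               else np.asarray(choice2, dtype=np.int64))
    if reward_probs is None:
        reward_probs = np.full((n, 2, 2), 0.5)
    if p_choice_a is None:
        p_choice_a = np.full(n, 0.5)
    base_meta = {"agent": "external", "agent_params": {},
                 "task_config": {"variant": "reduced"}, "seed": 0,
                 "n_trials": n}
    if meta:
        base_meta.update(meta)
    return Session(choice1, common, second_state, choice2, outcome,
                   np.asarray(p_choice_a, dtype=float), np.ones(n),
                   np.full((n, 2), 0.5), np.asarray(reward_probs, dtype=float),
                   base_meta)
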