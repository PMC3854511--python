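import numpy as np
import pytest

from mbdecide import cohort, learning, task


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def config():
    return task.TaskConfig()


@pytest.fixture(scope="session")
def sessions(config):
    """One subject's generated task (uniform random choices)."""
    return task.simulate_task(config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def stream(sessions):
    return learning.extract_stream(sessions)


@pytest.fixture(scope="session")
def subject():
    """One fully simulated synthetic subject at the default parameters."""
    return cohort.generate_subject(cohort.SubjectSpec(seed=42))


def random_stream(rng, n_trials, n_probes=0):
    """A synthetic transition stream (iid uniform images) for kernel-level tests."""
    obs = rng.integers(4, size=n_trials)
    prev = np.concatenate([[rng.integers(4)], obs[:-1]])
    if n_probes:
        pos = np.sort(rng.choice(n_trials, size=n_probes, replace=False))
        goal = rng.integers(4, size=n_probes)
    else:
        pos = np.empty(0, dtype=np.int64)
        goal = np.empty(0, dtype=np.int64)
    zeros = np.zeros(n_trials)
    zf = np.zeros(n_probes)
    return learning.TransitionStream(
        prev=prev.astype(np.int64),
        obs=obs.astype(np.int64),
        onset=np.arange(n_trials, dtype=float),
        session=np.zeros(n_trials, dtype=np.int64),
        is_outcome=np.zeros(n_trials, dtype=bool),
        is_probe_round=np.zeros(n_trials, dtype=bool),
        reward_shown=zeros.astype(np.int64),
        probe_pos=pos.astype(np.int64),
        probe_a=np.zeros(n_probes, dtype=np.int64),
        probe_b=np.ones(n_probes, dtype=np.int64),
        probe_goal=goal.astype(np.int64),
        probe_chosen=np.zeros(n_probes, dtype=np.int64),
        probe_value=np.ones(n_probes, dtype=np.int64),
        probe_session=np.zeros(n_probes, dtype=np.int64),
        probe_reward_onset=zf,
        probe_choice_onset=zf,
    )
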