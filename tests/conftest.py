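import numpy as np
import pytest

from contextsacc import SessionConfig, generate_session
from contextsacc.model import Trial


@pytest.fixture(scope="session")
def small_session():
    """A small but complete synthetic session shared across tests."""
    cfg = SessionConfig(n_per_context=3, n_trials_per_scene=6, n_units=6)
    return generate_session(cfg, seed=101)


@pytest.fixture(scope="session")
def default_session():
    """Default-condition session (10 scenes/context, 15 trials/scene,
    20 units) used by the heavier recovery tests."""
    return generate_session(seed=42)


def make_trials(n, prefix="", object_onset=1860.0):
    return [Trial(trial_id=f"{prefix}t{i:03d}", scene_id="s",
                  monkey_id="PA",
                  events={"scene_onset": 0.0, "fix_start": 1080.0,
                          "object_onset": object_onset},
                  first_object_value="good")
            for i in range(n)]


@pytest.fixture
def context_trials():
    """20 trials per context with canonical timing."""
    return {c: make_trials(20, c.replace("/", ""))
            for c in ("D/R", "S/R", "S/P")}
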