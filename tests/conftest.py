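import numpy as np
import pytest

from tmaze.maze import default_maze
from tmaze.mql import standard_queries
from tmaze.synthetic import NeuronSpec, SessionSpec, generate_spikes, generate_tracking


@pytest.fixture(scope="session")
def maze():
    return default_maze()


@pytest.fixture(scope="session")
def library(maze):
    return standard_queries(maze)


@pytest.fixture(scope="session")
def small_session():
    """A clean 24-trial synthetic session (no dropout) with ground truth."""
    rng = np.random.default_rng(1234)
    spec = SessionSpec(n_choice_trials=24, dropout_fraction=0.0, seed=1234)
    track, truth = generate_tracking(spec, rng=rng)
    return spec, track, truth


@pytest.fixture(scope="session")
def labelled_neurons(small_session):
    """Four neurons with known tuning (turn / trajectory / conjunctive / null)."""
    _, _, truth = small_session
    specs = [
        NeuronSpec(0, 5.0, turn_gain=4.0, preferred_turn="left"),
        NeuronSpec(1, 5.0, trajectory_gain=3.0, preferred_origin="R1"),
        NeuronSpec(
            2, 5.0, turn_gain=4.0, trajectory_gain=3.0,
            preferred_turn="right", preferred_origin="R2",
        ),
        NeuronSpec(3, 5.0),
    ]
    spikes = generate_spikes(truth, specs, rng=np.random.default_rng(99))
    return specs, spikes
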