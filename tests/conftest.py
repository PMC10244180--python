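import numpy as np
import pytest

from ovipost.ethogram import LABELS, LABEL_INDEX, Ethogram
from ovipost.simulate import EthogramSimParams, simulate_cohort


def make_ethogram(n_frames=200, fps=20.0, **kwargs):
    """Blank ethogram builder for hand-constructed test cases."""
    act = np.zeros((n_frames, len(LABELS)), dtype=bool)
    return Ethogram(activity=act, fps=fps, **kwargs), act


def set_active(act, label, start, end):
    act[start:end, LABEL_INDEX[label]] = True


def random_activity(rng, n_frames=120):
    """Random multi-label activity respecting the walk/burrow exclusion."""
    act = rng.random((n_frames, len(LABELS))) < 0.3
    act[:, LABEL_INDEX["walk"]] &= ~act[:, LABEL_INDEX["burrow"]]
    return act


@pytest.fixture(scope="session")
def cohort():
    """20 simulated egg-laying events shared across tests."""
    ethos, truths = simulate_cohort(EthogramSimParams(), n_events=20, n_flies=5, seed=42)
    return ethos, truths
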