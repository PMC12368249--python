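"""Shared fixtures: small ground-truthed synthetic datasets."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pytest

from optoneuro import synthetic
from optoneuro.types import NetworkModel, StimSchedule


@pytest.fixture(scope="session")
def chain_network() -> NetworkModel:
    """Three cells in a line, consecutive conduction delays of 0.5 s."""
    pos = np.array([[10.0, 10.0], [10.0, 30.0], [10.0, 50.0]])
    adj = np.array(
        [[False, True, False], [True, False, True], [False, True, False]]
    )
    delays = np.full((3, 3), np.nan)
    delays[0, 1] = delays[1, 0] = 0.5
    delays[1, 2] = delays[2, 1] = 0.5
    return NetworkModel(pos, adj, delays, stimulated_cell=0, field_shape=(20, 60))


@pytest.fixture(scope="session")
def single_pulse_stim() -> StimSchedule:
    return StimSchedule(np.array([1.0]), 0.010)


@pytest.fixture(scope="session")
def chain_movie(chain_network, single_pulse_stim):
    """Noiseless movie of the chain: activations at 1.0, 1.5, 2.0 s."""
    return synthetic.simulate_calcium_movie(
        chain_network, single_pulse_stim, frame_rate=30.0, duration=10.0,
        noise_sd=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def wave_movie():
    """Noiseless 50-cell propagating-wave movie with ground truth."""
    net = synthetic.generate_network(50, seed=7)
    stim = synthetic.make_stim_schedule(1.0, 0.010, 1.0, 5.0)
    movie, gt = synthetic.simulate_calcium_movie(
        net, stim, frame_rate=30.0, duration=20.0, noise_sd=0.0, seed=3
    )
    return net, movie, gt
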