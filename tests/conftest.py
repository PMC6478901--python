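"""Shared fixtures: generating parameters, small designs, simulated data."""

import numpy as np
import pandas as pd
import pytest

from flashbeep import bci_core, synthetic_data
from flashbeep.bci_core import BCIParams
from flashbeep.synthetic_data import ExperimentDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def table_params():
    """Group-mean generating parameters of the model-averaging observer."""
    return BCIParams(
        p_common=0.42, mu_p=2.26, sigma_p=2.34, sigma_a=0.53, sigma_v=1.11
    )


@pytest.fixture(scope="session")
def full_design():
    """One participant's full design: 8 AV runs x 16 conditions x 10 trials."""
    rng = np.random.default_rng(11)
    return synthetic_data.make_design(ExperimentDesign(), participant=1, rng=rng)


@pytest.fixture(scope="session")
def sim_trials(table_params, full_design):
    """1280 simulated trials from the group-mean observer."""
    rng = np.random.default_rng(12)
    return bci_core.simulate_trials(table_params, full_design, rng)


@pytest.fixture(scope="session")
def small_group_wav(table_params):
    """w_AV table for a simulated 23-participant group."""
    from flashbeep import behavior_wav

    rng = np.random.default_rng(21)
    params = synthetic_data.draw_participant_params(rng, 23)
    frames = []
    for pid, p in enumerate(params, 1):
        d = synthetic_data.make_design(ExperimentDesign(), pid, rng)
        t = bci_core.simulate_trials(p, d, rng)
        frames.append(behavior_wav.compute_wav(t))
    return pd.concat(frames, ignore_index=True)
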