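import numpy as np
import pandas as pd
import pytest

from mswtk.stimgen import TrialDesign, generate_trial_table
from mswtk.synthetic_data import ObserverParams, simulate_choices


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def av_trials() -> pd.DataFrame:
    """One moderately sized audio-visual block with simulated choices."""
    rng = np.random.default_rng(777)
    design = TrialDesign(n_trials=1800, condition_weights=(0, 0, 0, 1, 2, 2, 1, 2, 2))
    trials = generate_trial_table(design, rng)
    simulate_choices(trials, ObserverParams(), rng)
    return trials


@pytest.fixture(scope="session")
def full_block() -> pd.DataFrame:
    """A full 9-condition block (510 trials) with simulated choices."""
    rng = np.random.default_rng(101)
    trials = generate_trial_table(TrialDesign(), rng)
    simulate_choices(trials, ObserverParams(), rng)
    return trials
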