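import numpy as np
import pytest

from clpr.model import ModelParams, simulate_dataset
from clpr.stimuli import StimulusDesign, generate_design_set


@pytest.fixture(scope="session")
def v4_params():
    """Reference sigmoidal-compression parameters used across analyses."""
    return ModelParams(variant=4, d=0.05, decnoise=0.15)


@pytest.fixture(scope="session")
def v4_dataset_20k(v4_params):
    """20,000 trials simulated from the winning two-parameter model."""
    rng = np.random.default_rng(20260920)
    stim = generate_design_set(StimulusDesign(n_per_cell=2500), rng)
    return simulate_dataset(stim, v4_params, rng)


@pytest.fixture(scope="session")
def v4_dataset_2k(v4_params):
    """Smaller variant-4 dataset for IO and summary tests."""
    rng = np.random.default_rng(7)
    stim = generate_design_set(StimulusDesign(n_per_cell=250), rng)
    return simulate_dataset(stim, v4_params, rng)
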