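import numpy as np
import pytest

from kinecal.data import ExperimentalData, SimulationEnsemble


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset(rng):
    """10 replicates x 11 timepoints x 2 observables of mildly noisy data."""
    times = np.arange(0.0, 11.0)
    values = np.abs(rng.normal(50.0, 5.0, size=(10, 11, 2)))
    return ExperimentalData(("A", "B"), times, values)


@pytest.fixture
def matched_ensemble(small_dataset, rng):
    """An ensemble statistically indistinguishable from small_dataset."""
    values = np.abs(rng.normal(50.0, 5.0, size=(10, 11, 2)))
    return SimulationEnsemble(small_dataset.observables, small_dataset.times, values)
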