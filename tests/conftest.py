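import numpy as np
import pytest

import spl


@pytest.fixture(scope="session")
def default_spec():
    """The benchmark study configuration: 5 replicates of 20x300 data."""
    return spl.SimulationSpec(seed=7)


@pytest.fixture(scope="session")
def study(default_spec):
    """Patterns plus the 5 replicate datasets of the benchmark study."""
    patterns, datasets = spl.make_replicates(default_spec)
    return patterns, datasets


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def noise_only_dataset(m: int, rows_per_class: int, seed: int) -> spl.LabeledDataset:
    """A labeled dataset with no planted pattern at all."""
    rng = np.random.default_rng(seed)
    t = 2 * rows_per_class
    return spl.LabeledDataset(
        A=spl.make_colored_noise(t, m, rng),
        y=np.r_[np.ones(rows_per_class), -np.ones(rows_per_class)],
    )
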