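import warnings

import numpy as np
import pytest

from viscml.curation import curate
from viscml.synthetic import SyntheticConfig, generate_dataset

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_dataset():
    """Curated synthetic dataset: 30 compounds x 4 temperatures, clean."""
    config = SyntheticConfig(
        n_compounds=30, temperatures_per_compound=4, noise_sd=0.02, seed=7
    )
    records, truth = generate_dataset(config)
    dataset, report = curate(records)
    return dataset, truth


@pytest.fixture(scope="session")
def medium_dataset():
    """Curated synthetic dataset at benchmark scale (for acceptance tests)."""
    config = SyntheticConfig(seed=0)  # 200 compounds x 5 temperatures
    records, truth = generate_dataset(config)
    dataset, report = curate(records)
    return dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
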