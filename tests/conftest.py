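import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from birt import GeneratorConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_1pl():
    """Small complete 1PL dataset with known truth (60 persons x 5 items)."""
    cfg = GeneratorConfig(n_persons=60, n_items=5, model_class="1PL", seed=3)
    data, truth = simulate_dataset(cfg)
    return data, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
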