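import warnings

import numpy as np
import pytest

from socialrl import load_config, simulate_study

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_study():
    """A 4+4-subject study at the default task scale, shared across tests."""
    cfg = load_config()
    cfg.cohort.n_cbmi = 4
    cfg.cohort.n_ema = 4
    return simulate_study(cfg, seed=2024)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
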