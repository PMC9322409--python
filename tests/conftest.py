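import numpy as np
import pytest
from hypothesis import settings

from corrcompat import substream

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def paper_grid():
    """The full study-condition grid run once and shared across tests:
    true correlations 0.45 and 0.24, n = 8..100 step 2, 10,000 replicates."""
    from corrcompat import GridConfig, run_grid
    import time

    cfg = GridConfig(master_seed=0)
    t0 = time.perf_counter()
    summaries = run_grid(cfg)
    elapsed = time.perf_counter() - t0
    return cfg, summaries, elapsed
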