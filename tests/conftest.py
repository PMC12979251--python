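import numpy as np
import pytest

from cpibind import SimCiteSeqConfig, simulate_citeseq, simulate_hashtags


@pytest.fixture(scope="session")
def small_citeseq():
    """A small CITE-seq dataset with treated/bound structure."""
    cfg = SimCiteSeqConfig(n_cells=1200, seed=42)
    return simulate_citeseq(cfg)


@pytest.fixture(scope="session")
def hashed_pool():
    """A 4-sample hashed pool with 5% doublets (benchmark-scale)."""
    return simulate_hashtags(2000, 4, 0.05, mu_pos=500, mu_neg=10, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
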