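import numpy as np
import pytest

from cspapi.cs_design import CSStructure, search_design


@pytest.fixture(scope="session")
def default_structure():
    return CSStructure(m0=12, block_size=4, blocks_per_group=4, num_groups=4)


@pytest.fixture(scope="session")
def optimized_design(default_structure):
    """A SIN-optimized 12x16 group matrix (100-draw search, fixed seed)."""
    res = search_design(default_structure, s=2, n_iter=100, seed=0)
    assert res.best_sin > 0.1
    return res


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
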