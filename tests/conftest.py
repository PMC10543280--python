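import numpy as np
import pytest

import multiomesim as m


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_grn():
    # genes 1 and 2 are TFs; 2 is also a target (1 -> 2)
    edges = [(1, 3, 2.0), (1, 4, 3.0), (2, 5, 1.5), (2, 6, 4.0), (1, 2, 1.0)]
    return m.load_grn(edges, 8)


@pytest.fixture
def small_lr():
    return m.load_lr_database([(7, 3, 2.0), (8, 5, 3.0)])
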