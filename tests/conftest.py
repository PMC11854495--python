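import numpy as np
import pytest

import rrscope as rr


@pytest.fixture(scope="session")
def normal5():
    """The fixed 5-neuron reference weight matrix."""
    return rr.fixture("normal5")


@pytest.fixture(scope="session")
def block_relation():
    """3+2 block relation whose lattice is the canonical quantum-logic case."""
    return rr.fixture("block_relation_3_2")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
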