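import numpy as np
import pytest

import gacnn as g


@pytest.fixture(scope="session")
def tiny_spec():
    """8x8x1 input, one conv (2 filters), one pool, no hidden layer."""
    return g.build_network((8, 8, 1), [2], pool_every=1, hidden_width=0)


@pytest.fixture(scope="session")
def small_spec():
    """12x12x1 input, two conv layers, hidden width 5 — backprop test bed."""
    return g.build_network((12, 12, 1), [2, 2], hidden_width=5)


@pytest.fixture(scope="session")
def synth_dataset():
    """Small synthetic two-class dataset shared across tests."""
    return g.generate_synthetic_dataset(n_per_class=20, image_size=16, n_patients=6, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
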