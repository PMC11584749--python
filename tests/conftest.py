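import numpy as np
import pytest

import hdscreen as hd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_table():
    """200 rule-labelled toy molecules (active iff aromatic ring)."""
    return hd.generate_toy_molecules(200, seed=42)


@pytest.fixture(scope="session")
def small_binary_memory():
    """A binary associative memory on low-dimensional random bipolar data."""
    rng = np.random.default_rng(7)
    samples = hd.random_bipolar(256, rng, size=60)
    labels = np.array([0, 1] * 30)
    return hd.build_associative_memory(samples, labels), samples, labels
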