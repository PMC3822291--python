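import numpy as np
import pytest

import synmap as sm


@pytest.fixture(scope="session")
def palette():
    return sm.load_default_palette()


@pytest.fixture(scope="session")
def hiragana():
    return sm.load_default_inventory("hiragana")


@pytest.fixture(scope="session")
def latin():
    return sm.load_default_inventory("latin")


@pytest.fixture(scope="session")
def small_dataset(palette):
    """One seeded default-weight cohort shared by read-only tests."""
    return sm.generate_dataset(sm.GeneratorConfig(seed=42), palette=palette)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
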