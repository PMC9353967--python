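import numpy as np
import pytest

from dta_transfer.synthetic_data import SyntheticWorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A small but fully structured world shared by read-only tests."""
    return generate_world(
        SyntheticWorldConfig(n_chemicals=60, n_proteins=40, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
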