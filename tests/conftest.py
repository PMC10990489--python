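import numpy as np
import pytest

from lbkit import datasets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reference_fits():
    """Bundled published (EC50, Etop) fit table."""
    return datasets.reference_fit_table()
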