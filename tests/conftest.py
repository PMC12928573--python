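import numpy as np
import pytest

from crossddi.synthetic import FragmentLibrary, make_dataset


@pytest.fixture(scope="session")
def library():
    return FragmentLibrary()


@pytest.fixture(scope="session")
def small_dataset():
    """40 drugs / 150 labeled pairs: enough signal for smoke-level training."""
    return make_dataset(n_drugs=40, n_pairs=150, noise=0.1, seed=11)


@pytest.fixture(scope="session")
def medium_dataset():
    """120 drugs / 900 labeled pairs for split/baseline statistics."""
    return make_dataset(n_drugs=120, n_pairs=900, noise=0.1, seed=23)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
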