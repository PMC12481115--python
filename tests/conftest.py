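import numpy as np
import pytest

from emgsynergy import make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny two-group dataset (fast): 3+3 subjects, 4 group-A synergies,
    one fractionated parent."""
    return make_dataset(subjects_A=3, subjects_B=3, k_A=4, n_fractionate=1,
                        seed=42)


def unit_rows(X):
    X = np.asarray(X, dtype=float)
    return X / np.linalg.norm(X, axis=1, keepdims=True)
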