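import numpy as np
import pytest

from btbcul3.synthetic_data import SyntheticComplexSpec, make_cn_complex


@pytest.fixture(scope="session")
def pentamer():
    """Ideal C5 ring without partner."""
    model, manifest = make_cn_complex(SyntheticComplexSpec(n_fold=5, partner=False, seed=7))
    return model, manifest


@pytest.fixture(scope="session")
def complex_fixture():
    """Engineered 5:1 ring-plus-partner fixture with contact manifest."""
    model, manifest = make_cn_complex(SyntheticComplexSpec(n_fold=5, partner=True, seed=7))
    return model, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
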