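import numpy as np
import pytest

from rccnet import SubtypeClassifier, default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def trained8k(params):
    """Classifier trained once per session on the default simulator at
    8,000 records per class (fixed seeds); shared by the slower tests."""
    model = SubtypeClassifier.from_generative(params, n_per_class=8000, seed=7)
    return model.fit(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
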