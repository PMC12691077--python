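import numpy as np
import pytest

from thermoroi.text_prior import CATEGORIES, load_text_bank


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_bank():
    return load_text_bank()


@pytest.fixture(scope="session")
def cat_index():
    return {c: i for i, c in enumerate(CATEGORIES)}
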