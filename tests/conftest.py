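import numpy as np
import pytest

import somward as sw


@pytest.fixture(scope="session")
def codebook():
    return sw.load_codebook()


@pytest.fixture(scope="session")
def example_responses():
    return sw.load_example_responses()


@pytest.fixture(scope="session")
def fixture_dataset():
    return sw.load_packaged_dataset()


#: coded rows for the five worked-example students
EXPECTED_CODES = {
    "S_46": (10, 8, 9, 7, 9, 9, 5, 6, 9, 9),
    "S_47": (9, 9, 2, 7, 8, 7, 8, 8, 2, 2),
    "S_48": (8, 10, 2, 8, 6, 8, 8, 7, 8, 8),
    "S_49": (10, 2, 9, 1, 1, 1, 7, 8, 8, 9),
    "S_50": (8, 9, 10, 2, 2, 9, 8, 8, 8, 2),
}


@pytest.fixture(scope="session")
def small_trained_map():
    """A deterministic 5x6 hex map trained on two separated blobs."""
    rng = np.random.default_rng(7)
    X = np.vstack([
        rng.normal([1, 1, 1], 0.2, size=(25, 3)),
        rng.normal([8, 8, 8], 0.2, size=(25, 3)),
    ])
    config = sw.SOMConfig(rows=5, cols=6, init="linear", epochs=30)
    return sw.train(X, config), X
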