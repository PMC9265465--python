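import numpy as np
import pytest

from fqdeg import datasets


@pytest.fixture(scope="session")
def score_matrix():
    """Packaged 49 x 3 docking-score table."""
    return datasets.load_score_matrix()


@pytest.fixture(scope="session")
def field_design():
    """(design, mox_energy, derivative10_blank_energy) from the field table."""
    return datasets.load_field_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
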