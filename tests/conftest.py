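import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_card():
    """A small synthetic card plus ground truth, shared across tests."""
    from dotgrid.synthetic import CardParams, generate_card

    params = CardParams(width=400, height=260, n_dots=60.0, seed=77)
    img, truth, table = generate_card(params)
    return img, truth, table


@pytest.fixture(scope="session")
def clustered_field():
    from dotgrid.synthetic import generate_clustered_field

    return generate_clustered_field(seed=1)
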