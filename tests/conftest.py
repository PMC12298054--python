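import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def binary_dataset():
    """Small binary phantom dataset shared across tests (32px, 30+30)."""
    from quanvit.phantom import generate_dataset

    return generate_dataset({"normal": 30, "polyp": 30}, image_size=32, seed=7)


@pytest.fixture(scope="session")
def multi_dataset():
    from quanvit.phantom import generate_dataset

    return generate_dataset(
        {c: 12 for c in ("normal", "hyperplastic", "adenomatous", "serrated")},
        image_size=32,
        seed=11,
    )
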