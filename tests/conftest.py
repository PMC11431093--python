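import numpy as np
import pytest

from mfreen import MultibandSeries


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def trivariate_integers(rng):
    """Small integer-valued 3-band series for oracle comparisons."""
    return MultibandSeries(rng.integers(0, 10, size=(12, 3)).astype(float))
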