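import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from motifnull.motif_core import Motif

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20161006)


@pytest.fixture
def random_motif_factory(rng):
    """Uniform random motifs of requested dimensions."""

    def make(N: int, L: int) -> Motif:
        arr = rng.integers(0, 4, size=(N, L))
        return Motif.from_array(arr)

    return make
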