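import numpy as np
import pytest

from cnvminer import BinaryMatrix, ProbeTrack
from cnvminer.simulate import worked_example_fixture


def random_binary(rng: np.random.Generator, m: int, n: int, density: float = 0.4) -> BinaryMatrix:
    """Random dense-ish binary matrix for oracle comparisons."""
    cells = (rng.random((m, n)) < density).astype(np.uint8)
    return BinaryMatrix(cells, track=ProbeTrack.default(m))


@pytest.fixture
def toy_example():
    """Reconstructed toy worked-example matrix and its mining parameters."""
    return worked_example_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
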