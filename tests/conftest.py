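import numpy as np
import pytest

from domrank import WinLossMatrix


def random_matrix(rng: np.random.Generator, n: int, max_count: int = 4) -> WinLossMatrix:
    """A random win-loss matrix over n individuals (letters as ids)."""
    counts = rng.integers(0, max_count + 1, size=(n, n))
    np.fill_diagonal(counts, 0)
    ids = [chr(ord("A") + i) for i in range(n)]
    return WinLossMatrix(period="2000-01", group="G1", sex="F", ids=ids, counts=counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20200913)
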