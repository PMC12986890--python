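import numpy as np
import pytest

from sfegat.graph_construction import GraphDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_graph_batch(rng, n=4, c=8, b=8, density=0.4):
    """A batch of symmetric zero-diagonal weighted graphs + features."""
    a = rng.normal(size=(n, c, c))
    a = (a + a.swapaxes(1, 2)) / 2
    keep = rng.random((n, c, c)) < density
    keep = np.triu(keep, 1)
    keep = keep | keep.swapaxes(1, 2)
    a = np.where(keep, np.abs(a) + 0.1, 0.0)
    for i in range(c):
        a[:, i, i] = 0.0
    h = rng.random((n, c, b))
    return h, a


@pytest.fixture
def graph_batch(rng):
    return random_graph_batch(rng)


@pytest.fixture
def small_graph_dataset(rng):
    h, a = random_graph_batch(rng, n=24, c=6, b=8)
    return GraphDataset(
        adjacency=a,
        features=h,
        labels=rng.integers(0, 4, size=24),
        channel_labels=[f"ch{i}" for i in range(6)],
    )
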