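import numpy as np
import pytest

from gafs.feature_table import FeatureTable, RegionAtlas


class QueuedRNG:
    """Deterministic stand-in for numpy Generator: integers/random values are
    dequeued in call order, letting tests force cut points, gene picks, etc."""

    def __init__(self, integers=(), randoms=()):
        self._ints = list(integers)
        self._rands = list(randoms)

    def integers(self, low, high=None, size=None):
        if size is not None:
            return np.array([self.integers(low, high) for _ in range(size)])
        v = self._ints.pop(0)
        hi = low if high is None else high
        assert (0 if high is None else low) <= v < hi, f"queued int {v} outside range"
        return v

    def random(self):
        return self._rands.pop(0)


@pytest.fixture
def queued_rng():
    return QueuedRNG


def make_table(values, labels, region_names=None, ids=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    atlas = RegionAtlas(tuple(region_names or (f"R{i:03d}" for i in range(n))))
    ids = list(ids or (f"S{i:04d}" for i in range(values.shape[0])))
    return FeatureTable(ids, list(labels), values, atlas)


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def two_cluster_table():
    """Six subjects, one informative region: class A around 1.0, B around 5.0."""
    vals = [[0.9], [1.0], [1.1], [4.9], [5.0], [5.1]]
    return make_table(vals, ["A", "A", "A", "B", "B", "B"])


def random_small_table(rng, max_m=30, max_n=5, n_classes=2):
    m = int(rng.integers(3 * n_classes * 2, max_m + 1))
    n = int(rng.integers(1, max_n + 1))
    labels = [f"C{i % n_classes}" for i in range(m)]
    values = rng.normal(size=(m, n))
    return make_table(values, labels)


@pytest.fixture
def random_table_factory():
    return random_small_table
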