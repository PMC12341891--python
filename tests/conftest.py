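import numpy as np
import pytest

from netstab import Graph, Partition, RandomState


@pytest.fixture
def triangle():
    return Graph.from_id_pairs([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def two_triangles():
    """Two disjoint triangles: unambiguous 2-community graph."""
    return Graph.from_id_pairs(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
    )


@pytest.fixture
def rng():
    return RandomState(12345)


def random_partition(n: int, gen: np.random.Generator, max_blocks: int | None = None):
    """Uniform random labeling of n elements into <= max_blocks groups."""
    k = int(gen.integers(1, (max_blocks or n) + 1))
    labels = gen.integers(0, k, size=n)
    return Partition.from_labels([str(i) for i in range(n)], labels.tolist())


def set_partitions(n: int):
    """All partitions of {0..n-1} as label tuples (restricted growth strings)."""
    out = []

    def grow(prefix, next_label):
        if len(prefix) == n:
            out.append(tuple(prefix))
            return
        for lab in range(next_label + 1):
            grow(prefix + [lab], max(next_label, lab + 1))

    grow([], 0)
    return out
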