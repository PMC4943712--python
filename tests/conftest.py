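import itertools

import numpy as np
import pytest

from peckorder import InteractionEvent, InteractionRecord, Tournament


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def linear4():
    """The four-animal linear example: A beats all, B beats C and D, C beats D."""
    return Tournament.from_edges(
        4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    )


@pytest.fixture
def cycle3():
    """A single 3-cycle: A beats B, B beats C, C beats A."""
    return Tournament.from_edges(3, [(0, 1), (1, 2), (2, 0)])


@pytest.fixture
def transitive3():
    """A beats B, B beats C, A beats C."""
    return Tournament.from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def toy_record():
    """Fill-in of one triad then a counterattack making it cyclic."""
    return InteractionRecord(
        ("A", "B", "C"),
        (
            InteractionEvent(0.0, "A", "B"),
            InteractionEvent(10.0, "B", "C"),
            InteractionEvent(20.0, "A", "C"),
            InteractionEvent(140.0, "C", "A"),
        ),
    )


def all_tournaments(n):
    """Exhaustive enumeration of all 2**C(n,2) tournaments on n vertices."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in itertools.product((0, 1), repeat=len(pairs)):
        edges = [(i, j) if b else (j, i) for b, (i, j) in zip(bits, pairs)]
        yield Tournament.from_edges(n, edges)
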