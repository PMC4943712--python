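"""Tournament graphs and triad transitivity.

A *tournament* is a complete directed graph: exactly one directed edge
between every pair of vertices.  Here a vertex is an animal and the edge
between a pair points from the currently dominant animal to the subordinate
one (the direction of the most recent attack).  Every 3-subset of vertices
(a *triad*) is either transitive (A beats B, B beats C, A beats C) or
intransitive (a 3-cycle).  A dominance hierarchy is *linear* exactly when
the tournament contains no intransitive triad, in which case the animals
can be totally ordered by the number of others each one beats.

The number of triads in a group of ``n`` is ``tau = C(n, 3)``.  A uniform
random tournament on ``n`` vertices is linear with probability
``n! / 2**(n*(n-1)/2)``: the numerator counts the transitive tournaments
(one per total order), the denominator all orientations.

Vertices are 0-based integer indices; external labels (animal names) are
mapped to indices by the record-analysis layer.
"""

from __future__ import annotations

import itertools
import math
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TriadConfiguration",
    "Tournament",
    "random_tournament",
    "classify_triad",
    "count_intransitive",
    "is_linear",
    "flip_edge",
    "intransitive_delta",
    "p_linear_random",
    "sample_linear_fraction",
]

MAX_GROUP_SIZE = 12  # simulations are validated for n = 3..7; supported 2..12


class TriadConfiguration(Enum):
    """Configuration of a complete triad: transitive or a 3-cycle."""

    TRANSITIVE = "transitive"
    INTRANSITIVE = "intransitive"


class Tournament:
    """A complete orientation of all pairs of ``n`` vertices.

    Stored as an ``(n, n)`` 0/1 adjacency matrix with ``adj[i, j] == 1``
    iff ``i`` currently beats ``j``.  The constructor enforces that exactly
    one direction is present for every pair (Rule 1 completeness) and that
    there are no self-edges.
    """

    __slots__ = ("_adj",)

    def __init__(self, adjacency: np.ndarray | Sequence[Sequence[int]]):
        adj = np.array(adjacency, dtype=np.int8)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        n = adj.shape[0]
        if n < 2:
            raise ValueError(f"tournament needs at least 2 vertices, got n={n}")
        if np.any(np.diag(adj) != 0):
            raise ValueError("self-edges are not allowed")
        off = ~np.eye(n, dtype=bool)
        if not np.all((adj + adj.T)[off] == 1):
            raise ValueError(
                "every pair must have exactly one direction (Rule 1 violated)"
            )
        self._adj = adj

    # -- basic properties ---------------------------------------------------
    @property
    def n(self) -> int:
        """Group size."""
        return self._adj.shape[0]

    @property
    def tau(self) -> int:
        """Number of triads, C(n, 3)."""
        return math.comb(self.n, 3)

    @property
    def adjacency(self) -> np.ndarray:
        """Copy of the 0/1 dominance matrix (row beats column)."""
        return self._adj.copy()

    def beats(self, i: int, j: int) -> bool:
        """True iff ``i`` currently dominates ``j``."""
        self._check_pair(i, j)
        return bool(self._adj[i, j])

    def direction(self, i: int, j: int) -> tuple[int, int]:
        """Return the pair as (winner, loser)."""
        return (i, j) if self.beats(i, j) else (j, i)

    def pairs(self) -> Iterator[tuple[int, int]]:
        """All unordered pairs (i < j), lexicographic."""
        return itertools.combinations(range(self.n), 2)

    def triads(self) -> list[tuple[int, int, int]]:
        """All 3-subsets as sorted tuples, lexicographic."""
        return list(itertools.combinations(range(self.n), 3))

    def edges(self) -> list[tuple[int, int]]:
        """Directed edges (winner, loser), one per pair."""
        return [self.direction(i, j) for i, j in self.pairs()]

    def out_degrees(self) -> np.ndarray:
        """Number of vertices each vertex beats (the score sequence)."""
        return self._adj.sum(axis=1)

    def copy(self) -> "Tournament":
        return Tournament(self._adj)

    def _check_pair(self, i: int, j: int) -> None:
        n = self.n
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise ValueError(f"invalid pair ({i}, {j}) for n={n}")

    def flip_edge(self, pair: tuple[int, int]) -> "Tournament":
        """Return a tournament differing from this one only in ``pair``."""
        return flip_edge(self, pair)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Tournament):
            return NotImplemented
        return self.n == other.n and np.array_equal(self._adj, other._adj)

    def __hash__(self):  # mutable by design via copies; not hashable
        raise TypeError("Tournament is not hashable")

    def __repr__(self) -> str:
        return f"Tournament(n={self.n}, edges={self.edges()})"

    # -- construction / serialization ---------------------------------------
    @classmethod
    def from_edges(cls, n: int, edges: Iterable[tuple[int, int]]) -> "Tournament":
        """Build from directed (winner, loser) edges, one per pair."""
        adj = np.zeros((n, n), dtype=np.int8)
        for i, j in edges:
            adj[i, j] = 1
        return cls(adj)

    def to_edge_text(self) -> str:
        """Edge-list text: header line then one 'winner<TAB>loser' per pair."""
        lines = [f"# tournament n={self.n}"]
        lines += [f"{i}\t{j}" for i, j in self.edges()]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edge_text(cls, text: str) -> "Tournament":
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("# tournament n="):
            raise ValueError("missing '# tournament n=<n>' header")
        n = int(lines[0].split("=", 1)[1])
        edges = []
        for ln in lines[1:]:
            i, j = ln.split("\t")
            edges.append((int(i), int(j)))
        return cls.from_edges(n, edges)

    def to_matrix_frame(self) -> pd.DataFrame:
        """Dense 0/1 dominance matrix as a DataFrame (row beats column)."""
        idx = list(range(self.n))
        return pd.DataFrame(self.adjacency, index=idx, columns=idx)

    def to_csv(self, path_or_buf) -> None:
        self.to_matrix_frame().to_csv(path_or_buf)

    @classmethod
    def from_csv(cls, path_or_buf) -> "Tournament":
        df = pd.read_csv(path_or_buf, index_col=0)
        return cls(df.to_numpy())


# -- free functions ----------------------------------------------------------

def random_tournament(n: int, rng: np.random.Generator | None = None) -> Tournament:
    """Draw a uniform random tournament: each pair is a fair coin flip.

    All ``2**(n*(n-1)/2)`` tournaments are equiprobable.
    """
    if n < 2:
        raise ValueError(f"group size must be >= 2, got n={n}")
    rng = np.random.default_rng(rng)
    adj = np.zeros((n, n), dtype=np.int8)
    bits = rng.integers(0, 2, size=math.comb(n, 2))
    for b, (i, j) in zip(bits, itertools.combinations(range(n), 2)):
        if b:
            adj[i, j] = 1
        else:
            adj[j, i] = 1
    return Tournament(adj)


def _validate_triad(t: Tournament, triad: Sequence[int]) -> tuple[int, int, int]:
    tri = tuple(triad)
    if len(tri) != 3 or len(set(tri)) != 3:
        raise ValueError(f"invalid triad {triad!r}: need 3 distinct vertices")
    for v in tri:
        if not (isinstance(v, (int, np.integer)) and 0 <= v < t.n):
            raise ValueError(f"invalid triad {triad!r} for n={t.n}")
    return tri  # type: ignore[return-value]


def classify_triad(t: Tournament, triad: Sequence[int]) -> TriadConfiguration:
    """Label a 3-subset TRANSITIVE or INTRANSITIVE (3-cycle)."""
    a, b, c = _validate_triad(t, triad)
    adj = t._adj
    cyclic = (adj[a, b] and adj[b, c] and adj[c, a]) or (
        adj[b, a] and adj[c, b] and adj[a, c]
    )
    return TriadConfiguration.INTRANSITIVE if cyclic else TriadConfiguration.TRANSITIVE


def count_intransitive(t: Tournament) -> int:
    """Brute-force census: number of intransitive (cyclic) triads."""
    return sum(
        classify_triad(t, tri) is TriadConfiguration.INTRANSITIVE
        for tri in t.triads()
    )


def is_linear(t: Tournament) -> bool:
    """True iff the hierarchy is linear (no intransitive triad).

    Equivalent to the score sequence being a permutation of 0..n-1.
    """
    scores = np.sort(t.out_degrees())
    return bool(np.array_equal(scores, np.arange(t.n)))


def flip_edge(t: Tournament, pair: tuple[int, int]) -> Tournament:
    """Reverse the direction of one pair; all other pairs unchanged."""
    i, j = pair
    t._check_pair(i, j)
    adj = t.adjacency
    adj[i, j], adj[j, i] = adj[j, i], adj[i, j]
    return Tournament(adj)


def intransitive_delta(t: Tournament, pair: tuple[int, int]) -> int:
    """Change in the intransitive-triad count if ``pair`` were flipped.

    Only the ``n - 2`` triads containing the flipped pair can change label,
    so this is O(n) rather than a full O(n^3) recount.
    """
    i, j = pair
    t._check_pair(i, j)
    adj = t._adj
    delta = 0
    for k in range(t.n):
        if k == i or k == j:
            continue
        cyc_before = (adj[i, j] and adj[j, k] and adj[k, i]) or (
            adj[j, i] and adj[k, j] and adj[i, k]
        )
        # after flipping {i, j}: i->j becomes j->i and vice versa
        cyc_after = (adj[j, i] and adj[j, k] and adj[k, i]) or (
            adj[i, j] and adj[k, j] and adj[i, k]
        )
        delta += int(bool(cyc_after)) - int(bool(cyc_before))
    return delta


def p_linear_random(n: int) -> float:
    """Probability that a uniform random tournament on ``n`` is linear.

    Closed form ``n! / 2**(n*(n-1)/2)``: transitive tournaments are in
    bijection with total orders of the vertices.
    """
    if n < 2:
        raise ValueError(f"group size must be >= 2, got n={n}")
    return math.factorial(n) / 2 ** math.comb(n, 2)


def sample_linear_fraction(
    n: int, draws: int, rng: np.random.Generator | None = None
) -> float:
    """Monte-Carlo estimate of the random-tournament linearity probability.

    Vectorized over ``draws`` independent uniform tournaments; linearity is
    checked via the score-sequence criterion.
    """
    if n < 2:
        raise ValueError(f"group size must be >= 2, got n={n}")
    rng = np.random.default_rng(rng)
    pairs = list(itertools.combinations(range(n), 2))
    bits = rng.integers(0, 2, size=(draws, len(pairs)), dtype=np.int8)
    scores = np.zeros((draws, n), dtype=np.int16)
    for col, (i, j) in enumerate(pairs):
        b = bits[:, col]
        scores[:, i] += b
        scores[:, j] += 1 - b
    scores.sort(axis=1)
    target = np.arange(n, dtype=np.int16)
    return float(np.mean(np.all(scores == target, axis=1)))
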