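"""Synthetic aggression-record generator.

Produces timestamped event logs with exactly the statistical structure the
dynamical model assumes, so the record-analysis layer can be validated
end-to-end with known ground truth (no hen data are publicly deposited).

Phase 1 (Rule 1 fill-in): one attack per pair, fair-coin direction, pairs
in a random order by default — after ``n*(n-1)/2`` events every pair has a
direction and the group carries a complete tournament.

Phase 2 (Rule 2 dynamics): each subsequent event is one step of the Markov
process.  A triad is selected uniformly; if an alpha- or beta-conversion
fires, the emitted event is the reversing attack; otherwise the event is a
repeat attack along a uniformly chosen existing edge of the selected
triad.  Every step therefore emits exactly one observable peck, so episode
durations are well defined both in interactions and in seconds.

Inter-event times are i.i.d. exponential.  The default mean gap of 150 s
matches the order of magnitude seen in small hen groups (a few attacks per
ten minutes); there is no time-of-day or burst structure.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass


import numpy as np

from .records import InteractionEvent, InteractionRecord, EXPECTED_COLUMNS
from .tournament import Tournament, TriadConfiguration, classify_triad, flip_edge

__all__ = ["GeneratorConfig", "default_roster", "generate_record", "write_events"]


def default_roster(n: int) -> tuple[str, ...]:
    """Letter labels A, B, ... for small n, zero-padded IDs beyond 26."""
    if n <= 26:
        return tuple(string.ascii_uppercase[:n])
    return tuple(f"ID{i:03d}" for i in range(n))


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters of a synthetic record.

    ``n_events`` counts all emitted events including the fill-in phase and
    must be at least ``n*(n-1)/2``.  ``mean_interval_s`` is the mean of the
    exponential inter-event gaps, in seconds.  ``fill_in_order`` is
    "random" (default) or "lex".
    """

    n: int
    alpha: float
    beta: float
    n_events: int
    mean_interval_s: float = 150.0
    seed: int = 0
    fill_in_order: str = "random"

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got n={self.n}")
        for name, p in (("alpha", self.alpha), ("beta", self.beta)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_events < math.comb(self.n, 2):
            raise ValueError(
                f"n_events={self.n_events} below the fill-in minimum "
                f"{math.comb(self.n, 2)} for n={self.n}"
            )
        if self.mean_interval_s <= 0:
            raise ValueError("mean_interval_s must be positive")
        if self.fill_in_order not in ("random", "lex"):
            raise ValueError("fill_in_order must be 'random' or 'lex'")


def generate_record(config: GeneratorConfig) -> InteractionRecord:
    """Generate a record: Rule 1 fill-in, then Rule 2 Markov dynamics.

    Deterministic given ``config.seed``.  The tournament implied by the
    record (most-recent directions) follows the same law as the simulator
    chain with the same (n, alpha, beta).
    """
    rng = np.random.default_rng(config.seed)
    roster = default_roster(config.n)
    n = config.n
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if config.fill_in_order == "random":
        order = rng.permutation(len(pairs))
    else:
        order = np.arange(len(pairs))

    gaps = rng.exponential(config.mean_interval_s, size=config.n_events)
    times = np.cumsum(gaps)

    events: list[InteractionEvent] = []
    adj = np.zeros((n, n), dtype=np.int8)
    for k in order:
        i, j = pairs[k]
        if rng.integers(0, 2):
            w, l = i, j
        else:
            w, l = j, i
        adj[w, l] = 1
        events.append(InteractionEvent(float(times[len(events)]), roster[w], roster[l]))

    t = Tournament(adj)
    triads = t.triads()
    tau = len(triads)
    for _ in range(config.n_events - len(pairs)):
        tri = triads[int(rng.integers(tau))] if tau else None
        if tri is None:  # n = 2: only repeats are possible
            i, j = t.direction(0, 1)
            events.append(InteractionEvent(float(times[len(events)]), roster[i], roster[j]))
            continue
        a, b, c = tri
        tri_pairs = ((a, b), (a, c), (b, c))
        y = float(rng.random())
        if classify_triad(t, tri) is TriadConfiguration.INTRANSITIVE:
            if y <= config.alpha:
                pair = tri_pairs[int(rng.integers(3))]
                cur_w, cur_l = t.direction(*pair)
                t = flip_edge(t, pair)
                # the reversing attack: current loser counterattacks
                events.append(
                    InteractionEvent(float(times[len(events)]), roster[cur_l], roster[cur_w])
                )
                continue
        else:
            if y <= config.beta:
                wins = {v: int(t.beats(v, u)) + int(t.beats(v, w))
                        for v, u, w in ((a, b, c), (b, a, c), (c, a, b))}
                dominant = max(tri, key=lambda v: wins[v])
                bottom = min(tri, key=lambda v: wins[v])
                t = flip_edge(t, (dominant, bottom))
                events.append(
                    InteractionEvent(float(times[len(events)]), roster[bottom], roster[dominant])
                )
                continue
        # no conversion: repeat attack along an existing edge of the triad
        pair = tri_pairs[int(rng.integers(3))]
        w, l = t.direction(*pair)
        events.append(InteractionEvent(float(times[len(events)]), roster[w], roster[l]))

    return InteractionRecord(roster=roster, events=tuple(events))


def write_events(record: InteractionRecord, sink) -> None:
    """Write a record in the TSV event format read by ``read_events``.

    ``repr``-precision float times, so write -> read round-trips exactly.
    """

    def _write(fh):
        fh.write("\t".join(EXPECTED_COLUMNS) + "\n")
        for ev in record.events:
            fh.write(f"{ev.time_s!r}\t{ev.actor}\t{ev.recipient}\n")

    if hasattr(sink, "write"):
        _write(sink)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            _write(fh)
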