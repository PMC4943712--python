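"""Analysis of timestamped dyadic aggression records.

The raw data of hierarchy formation is an event log: at time ``t`` animal
``actor`` attacked animal ``recipient``.  From such a log this module

* maintains the dynamic tournament of most-recent attack directions,
* extracts *triad episodes* — maximal spells during which one triad's three
  directions are unchanged — labelled transitive or intransitive, with
  durations measured both in group interactions and in seconds,
* tracks the per-event linear/non-linear status of the whole hierarchy and
  counts switches,
* reproduces the classical static abstraction chain: windowed attack-count
  matrix -> pairwise dominance relations -> rank order,
* estimates the two conversion probabilities (alpha, beta) from observed
  episode terminations, closing the loop with the synthetic generator.

Under the dynamical model, intransitive episodes should be much shorter
than transitive ones (Rule 2) — typically by an order of magnitude in the
small hen groups that motivated the model.

Event files are plain TSV with a ``time_s / actor / recipient`` header;
times are seconds from observation start and must be non-decreasing, with
file order authoritative for simultaneous events.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tournament import Tournament, TriadConfiguration, count_intransitive

__all__ = [
    "InteractionEvent",
    "InteractionRecord",
    "TriadEpisode",
    "DominanceMatrix",
    "PartialTournament",
    "RecordValidationError",
    "EmptyRecordError",
    "UndefinedRateError",
    "read_events",
    "current_tournament",
    "episodes",
    "episode_summary",
    "EpisodeSummary",
    "linearity_timeline",
    "attack_matrix",
    "dominance_relations",
    "rank_order",
    "RankOrder",
    "estimate_rates",
    "RateEstimates",
    "split_sessions",
    "plot_record",
]

EXPECTED_COLUMNS = ("time_s", "actor", "recipient")


class RecordValidationError(ValueError):
    """An event file failed validation; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyRecordError(RecordValidationError):
    """The event file contains no data rows."""


class UndefinedRateError(ValueError):
    """Rate estimation requested on a record with no closed episodes."""


@dataclass(frozen=True)
class InteractionEvent:
    """One directed aggressive act: actor attacks recipient at time_s."""

    time_s: float
    actor: str
    recipient: str

    def __post_init__(self):
        if self.actor == self.recipient:
            raise ValueError(f"self-attack: {self.actor} -> {self.recipient}")
        if self.time_s < 0:
            raise ValueError(f"negative time {self.time_s}")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.actor, self.recipient)))  # type: ignore[return-value]


@dataclass(frozen=True)
class InteractionRecord:
    """A time-ordered sequence of attacks among a named roster."""

    roster: tuple[str, ...]
    events: tuple[InteractionEvent, ...]
    sessions: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self):
        members = set(self.roster)
        for k, ev in enumerate(self.events):
            if ev.actor not in members or ev.recipient not in members:
                raise ValueError(f"event {k}: {ev.actor}->{ev.recipient} not in roster")
            if k and ev.time_s < self.events[k - 1].time_s:
                raise ValueError(f"event {k}: decreasing timestamp {ev.time_s}")

    @property
    def n(self) -> int:
        return len(self.roster)

    def __len__(self) -> int:
        return len(self.events)

    def index(self) -> dict[str, int]:
        """Stable label -> 0-based vertex index mapping (roster order)."""
        return {name: i for i, name in enumerate(self.roster)}


def split_sessions(record: InteractionRecord) -> list[InteractionRecord]:
    """One sub-record per observation session (half-open windows).

    Sessions (e.g. separate observation days) are analysed independently
    by default — episodes do not continue across a session boundary, since
    the configuration during unobserved gaps is unknown.  A record without
    session metadata is returned whole.  Concatenating across sessions is
    the explicit alternative: simply analyse the parent record.
    """
    if not record.sessions:
        return [record]
    out = []
    for start_s, end_s in record.sessions:
        evs = tuple(e for e in record.events if start_s <= e.time_s < end_s)
        out.append(InteractionRecord(roster=record.roster, events=evs))
    return out


@dataclass(frozen=True)
class TriadEpisode:
    """One uninterrupted configuration spell of one triad.

    ``start_event_index`` is the 0-based index of the event that
    established the configuration (the fill-in completion or the reversal
    opening the spell); ``end_event_index`` is the terminating reversal
    (None when censored at record end).  ``duration_interactions`` counts
    group events strictly after the start event up to and including the
    terminating event (up to the last event for censored spells).
    """

    triad: tuple[str, str, str]
    configuration: TriadConfiguration
    start_event_index: int
    end_event_index: int | None
    duration_interactions: int
    duration_s: float
    censored: bool


@dataclass(frozen=True)
class DominanceMatrix:
    """Windowed attack-frequency matrix: entry (i, j) = attacks by i on j."""

    window: tuple[float, float]
    counts: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass(frozen=True)
class PartialTournament:
    """Most-recent attack directions for the pairs observed so far."""

    roster: tuple[str, ...]
    directions: dict[tuple[str, str], tuple[str, str]]  # sorted pair -> (winner, loser)

    @property
    def n_pairs(self) -> int:
        return math.comb(len(self.roster), 2)

    @property
    def is_complete(self) -> bool:
        """True iff every pair has interacted (Rule 1 satisfied so far)."""
        return len(self.directions) == self.n_pairs

    def missing_pairs(self) -> list[tuple[str, str]]:
        return [
            p
            for p in itertools.combinations(sorted(self.roster), 2)
            if p not in self.directions
        ]

    def to_tournament(self) -> Tournament:
        """Convert to an integer-vertex Tournament (requires completeness)."""
        if not self.is_complete:
            raise ValueError(f"tournament incomplete: missing {self.missing_pairs()}")
        idx = {name: i for i, name in enumerate(self.roster)}
        edges = [(idx[w], idx[l]) for (w, l) in self.directions.values()]
        return Tournament.from_edges(len(self.roster), edges)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_events(source, roster: Sequence[str] | None = None) -> InteractionRecord:
    """Read a TSV event log (columns time_s, actor, recipient; extras ignored).

    Rejects self-attacks and decreasing timestamps with the offending line
    number (header = line 1).  The roster defaults to the union of observed
    IDs, sorted.
    """
    df = pd.read_csv(
        source, sep="\t", dtype={"actor": str, "recipient": str},
        float_precision="round_trip",
    )
    missing = [c for c in EXPECTED_COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError(f"missing column(s) {missing}", line=1)
    if len(df) == 0:
        raise EmptyRecordError("no event rows", line=1)
    times = df["time_s"].to_numpy(dtype=float)
    events = []
    prev = -np.inf
    for k in range(len(df)):
        line = k + 2  # header is line 1
        actor, recipient = df["actor"].iat[k], df["recipient"].iat[k]
        t = float(times[k])
        if actor == recipient:
            raise RecordValidationError(f"self-attack {actor} -> {recipient}", line=line)
        if not np.isfinite(t) or t < 0:
            raise RecordValidationError(f"bad time {t}", line=line)
        if t < prev:
            raise RecordValidationError(f"decreasing timestamp {t}", line=line)
        prev = t
        events.append(InteractionEvent(t, actor, recipient))
    if roster is None:
        roster = sorted({e.actor for e in events} | {e.recipient for e in events})
    return InteractionRecord(roster=tuple(roster), events=tuple(events))


# ---------------------------------------------------------------------------
# dynamic tournament
# ---------------------------------------------------------------------------

def current_tournament(record: InteractionRecord, upto: int | None = None) -> PartialTournament:
    """Most-recent attack directions after the first ``upto`` events.

    ``upto`` is a count of events (0 = nothing observed; None = all).
    Pairs never observed are absent; ``is_complete`` reports whether Rule 1
    holds so far.
    """
    if upto is None:
        upto = len(record.events)
    if not (0 <= upto <= len(record.events)):
        raise ValueError(f"upto={upto} out of range for {len(record.events)} events")
    directions: dict[tuple[str, str], tuple[str, str]] = {}
    for ev in record.events[:upto]:
        directions[ev.pair] = (ev.actor, ev.recipient)
    return PartialTournament(roster=record.roster, directions=directions)


def _triad_config(directions, tri) -> TriadConfiguration:
    """Classify a complete named triad from pair directions."""
    a, b, c = tri
    winners = {p: directions[p][0] for p in
               (tuple(sorted((a, b))), tuple(sorted((a, c))), tuple(sorted((b, c))))}
    beats = set(directions[p] for p in winners)
    # cyclic iff each vertex wins exactly one of its two pairs
    wins = {v: 0 for v in tri}
    for w, _ in beats:
        wins[w] += 1
    cyclic = sorted(wins.values()) == [1, 1, 1]
    return TriadConfiguration.INTRANSITIVE if cyclic else TriadConfiguration.TRANSITIVE


# ---------------------------------------------------------------------------
# episodes
# ---------------------------------------------------------------------------

def episodes(
    record: InteractionRecord, interactions: str = "group"
) -> list[TriadEpisode]:
    """Extract configuration episodes for every triad of the roster.

    A triad's first episode starts at the event completing its third pair;
    an episode ends at the first later event reversing any of its three
    current directions (that event opens the next episode).  The final
    episode of each triad is censored at the last event.

    ``interactions`` selects the duration unit: "group" (default) counts
    all events in the group between start (exclusive) and end (inclusive);
    "triad" counts only events among the triad's three members.
    """
    if interactions not in ("group", "triad"):
        raise ValueError(f"interactions must be 'group' or 'triad', got {interactions!r}")
    if record.n < 3 or not record.events:
        return []
    triads = list(itertools.combinations(sorted(record.roster), 3))
    tri_pairs = {
        tri: [tuple(sorted(p)) for p in itertools.combinations(tri, 2)] for tri in triads
    }
    pair_triads: dict[tuple[str, str], list[tuple[str, str, str]]] = {}
    for tri, prs in tri_pairs.items():
        for p in prs:
            pair_triads.setdefault(p, []).append(tri)

    directions: dict[tuple[str, str], tuple[str, str]] = {}
    # per-triad open-episode state
    open_ep: dict[tuple[str, str, str], dict] = {}
    tri_event_count: dict[tuple[str, str, str], int] = {t: 0 for t in triads}
    out: list[TriadEpisode] = []
    times = [e.time_s for e in record.events]

    def open_episode(tri, idx):
        open_ep[tri] = {
            "config": _triad_config(directions, tri),
            "start": idx,
            "tri_count_at_start": tri_event_count[tri],
        }

    def close_episode(tri, idx):
        st = open_ep[tri]
        if interactions == "group":
            dur = idx - st["start"]
        else:
            dur = tri_event_count[tri] - st["tri_count_at_start"]
        out.append(
            TriadEpisode(
                triad=tri,
                configuration=st["config"],
                start_event_index=st["start"],
                end_event_index=idx,
                duration_interactions=dur,
                duration_s=times[idx] - times[st["start"]],
                censored=False,
            )
        )

    for idx, ev in enumerate(record.events):
        pair = ev.pair
        new_dir = (ev.actor, ev.recipient)
        old_dir = directions.get(pair)
        reversal = old_dir is not None and old_dir != new_dir
        directions[pair] = new_dir
        for tri in pair_triads.get(pair, []):
            tri_event_count[tri] += 1
        for tri in pair_triads.get(pair, []):
            if tri in open_ep:
                if reversal:
                    close_episode(tri, idx)
                    open_episode(tri, idx)
            else:
                if all(p in directions for p in tri_pairs[tri]):
                    open_episode(tri, idx)

    last = len(record.events) - 1
    for tri in triads:
        if tri in open_ep:
            st = open_ep[tri]
            if interactions == "group":
                dur = last - st["start"]
            else:
                dur = tri_event_count[tri] - st["tri_count_at_start"]
            out.append(
                TriadEpisode(
                    triad=tri,
                    configuration=st["config"],
                    start_event_index=st["start"],
                    end_event_index=None,
                    duration_interactions=dur,
                    duration_s=times[last] - times[st["start"]],
                    censored=True,
                )
            )
    out.sort(key=lambda e: (e.triad, e.start_event_index))
    return out


@dataclass(frozen=True)
class EpisodeSummary:
    """Per-configuration duration statistics of closed episodes.

    ``by_configuration`` has one row per configuration with closed-episode
    count, mean/median durations in interactions and seconds, and the
    censored tally.  Censored episodes are excluded from means and medians
    (their durations are lower bounds).
    """

    by_configuration: pd.DataFrame
    n_triads: int
    n_triads_ever_intransitive: int
    fraction_triads_ever_intransitive: float
    duration_ratio_interactions: float  # transitive mean / intransitive mean
    duration_ratio_seconds: float


def episode_summary(eps: Sequence[TriadEpisode]) -> EpisodeSummary:
    """Summarize episode durations by configuration type."""
    labels = [c.value for c in (TriadConfiguration.TRANSITIVE, TriadConfiguration.INTRANSITIVE)]
    rows = {}
    for lab in labels:
        closed = [e for e in eps if e.configuration.value == lab and not e.censored]
        cens = [e for e in eps if e.configuration.value == lab and e.censored]
        di = np.array([e.duration_interactions for e in closed], dtype=float)
        ds = np.array([e.duration_s for e in closed], dtype=float)
        rows[lab] = {
            "n_closed": len(closed),
            "n_censored": len(cens),
            "mean_interactions": float(di.mean()) if len(di) else 0.0,
            "median_interactions": float(np.median(di)) if len(di) else 0.0,
            "mean_seconds": float(ds.mean()) if len(ds) else 0.0,
            "median_seconds": float(np.median(ds)) if len(ds) else 0.0,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "configuration"
    triads = {e.triad for e in eps}
    ever_int = {
        e.triad for e in eps if e.configuration is TriadConfiguration.INTRANSITIVE
    }
    ti, ii = rows[labels[0]], rows[labels[1]]

    def ratio(a, b):
        return a / b if b > 0 else float("nan")

    return EpisodeSummary(
        by_configuration=df,
        n_triads=len(triads),
        n_triads_ever_intransitive=len(ever_int),
        fraction_triads_ever_intransitive=(
            len(ever_int) / len(triads) if triads else 0.0
        ),
        duration_ratio_interactions=ratio(
            ti["mean_interactions"], ii["mean_interactions"]
        ) if ii["n_closed"] else float("nan"),
        duration_ratio_seconds=ratio(ti["mean_seconds"], ii["mean_seconds"])
        if ii["n_closed"]
        else float("nan"),
    )


# ---------------------------------------------------------------------------
# linearity timeline
# ---------------------------------------------------------------------------

UNDEFINED, LINEAR, NONLINEAR = "UNDEFINED", "LINEAR", "NONLINEAR"


def linearity_timeline(record: InteractionRecord) -> tuple[list[str], int]:
    """Hierarchy status after each event, and the number of switches.

    Status is UNDEFINED while some pair has never interacted, else LINEAR
    or NONLINEAR.  The switch count is the number of LINEAR <-> NONLINEAR
    transitions (entering from UNDEFINED is not a switch).

    The intransitive-triad count is maintained incrementally: only the
    n - 2 triads through a reversed pair can change label, so the whole
    timeline is O(events * n).
    """
    idx = record.index()
    n = record.n
    adj = np.zeros((n, n), dtype=np.int8)
    seen: set[frozenset[int]] = set()
    total_pairs = math.comb(n, 2)
    count: int | None = None  # intransitive triads, once complete
    statuses: list[str] = []
    switches = 0
    prev = UNDEFINED
    for ev in record.events:
        i, j = idx[ev.actor], idx[ev.recipient]
        if count is None:
            adj[i, j], adj[j, i] = 1, 0
            seen.add(frozenset((i, j)))
            if len(seen) == total_pairs:
                count = count_intransitive(Tournament(adj))
        elif adj[i, j] == 0:  # reversal of an established direction
            delta = 0
            for k in range(n):
                if k != i and k != j:
                    # pre-flip j beats i: triad cyclic iff j->i->k->j
                    before = adj[i, k] and adj[k, j]
                    # post-flip i beats j: cyclic iff i->j->k->i
                    after = adj[j, k] and adj[k, i]
                    delta += int(bool(after)) - int(bool(before))
            adj[i, j], adj[j, i] = 1, 0
            count += delta
        if count is None:
            status = UNDEFINED
        else:
            status = LINEAR if count == 0 else NONLINEAR
        if prev != UNDEFINED and status != UNDEFINED and status != prev:
            switches += 1
        statuses.append(status)
        prev = status
    return statuses, switches


# ---------------------------------------------------------------------------
# static abstraction chain: matrix -> relations -> ranks
# ---------------------------------------------------------------------------

def attack_matrix(
    record: InteractionRecord, window: tuple[float, float] | None = None
) -> DominanceMatrix:
    """Count attacks per ordered pair within a half-open time window.

    Events with ``start_s <= time < end_s`` are counted; ``window=None``
    spans the whole record.
    """
    if window is None:
        window = (0.0, float("inf"))
    start_s, end_s = window
    if not start_s < end_s:
        raise ValueError(f"inverted window ({start_s}, {end_s})")
    roster = list(record.roster)
    counts = pd.DataFrame(0, index=roster, columns=roster, dtype=int)
    for ev in record.events:
        if start_s <= ev.time_s < end_s:
            counts.loc[ev.actor, ev.recipient] += 1
    return DominanceMatrix(window=(start_s, end_s), counts=counts)


def dominance_relations(
    m: DominanceMatrix, threshold: float = 0.5
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Pairwise dominance from windowed counts.

    ``i`` dominates ``j`` iff its share of the pair's attacks strictly
    exceeds ``threshold`` (default 0.5: strict majority).  Pairs with no
    decisive direction — including 0-0 — are returned as undetermined.
    """
    if not 0.5 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0.5, 1), got {threshold}")
    roster = list(m.counts.index)
    relations: set[tuple[str, str]] = set()
    undetermined: set[tuple[str, str]] = set()
    for i, j in itertools.combinations(roster, 2):
        cij, cji = int(m.counts.loc[i, j]), int(m.counts.loc[j, i])
        tot = cij + cji
        if tot > 0 and cij / tot > threshold:
            relations.add((i, j))
        elif tot > 0 and cji / tot > threshold:
            relations.add((j, i))
        else:
            undetermined.add(tuple(sorted((i, j))))  # type: ignore[arg-type]
    return relations, undetermined


@dataclass(frozen=True)
class RankOrder:
    """Individuals ordered by number dominated, with a linearity flag."""

    order: tuple[str, ...]
    scores: dict[str, int]
    is_linear: bool
    complete: bool


def rank_order(
    relations: Iterable[tuple[str, str]], roster: Sequence[str]
) -> RankOrder:
    """Sort individuals by how many others they dominate.

    The hierarchy is flagged linear only when the relations are complete
    (every pair decided) and the scores are the distinct values 0..n-1.
    Ties in score are broken alphabetically for a deterministic order.
    """
    roster = list(roster)
    relations = set(relations)
    scores = {r: 0 for r in roster}
    for w, _l in relations:
        scores[w] += 1
    complete = len(relations) == math.comb(len(roster), 2)
    linear = complete and sorted(scores.values()) == list(range(len(roster)))
    order = tuple(sorted(roster, key=lambda r: (-scores[r], r)))
    return RankOrder(order=order, scores=scores, is_linear=linear, complete=complete)


# ---------------------------------------------------------------------------
# rate estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateEstimates:
    """Per-triad conversion-probability estimates from episode terminations.

    ``alpha_hat`` is the per-opportunity intransitive-to-transitive
    conversion frequency, ``beta_hat`` the transitive-to-intransitive one;
    both are scaled by the number of triads so that they estimate the
    per-selected-triad probabilities of the Markov model (for n = 3,
    tau = 1, this is exactly conversions / interactions-at-risk).
    Confidence intervals are Clopper-Pearson, scaled the same way.
    """

    alpha_hat: float
    beta_hat: float
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    alpha_defined: bool
    beta_defined: bool
    n_intransitive_trials: int
    n_intransitive_conversions: int
    n_transitive_trials: int
    n_transitive_to_intransitive: int
    tau_scale: float


def _clopper_pearson(k: int, n: int, confidence: float) -> tuple[float, float]:
    a = 1.0 - confidence
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - a / 2, k + 1, n - k))
    return lo, hi


def estimate_rates(
    record: InteractionRecord,
    confidence: float = 0.95,
    scale_to_triads: bool = True,
) -> RateEstimates:
    """Estimate (alpha, beta) from observed episode durations.

    Every group interaction during an episode is one Bernoulli opportunity
    for the triad to convert; alpha_hat uses closed intransitive episodes
    (any reversal of a 3-cycle yields a transitive triad), beta_hat uses
    transitive episodes whose successor configuration is intransitive.
    With ``scale_to_triads`` the per-event frequencies are multiplied by
    tau = C(n, 3), since the model selects a specific triad with
    probability 1/tau per event.  Exact for n = 3; for larger n,
    terminations caused by overlapping triads bias the estimates slightly
    upward.
    """
    eps = episodes(record)
    closed = [e for e in eps if not e.censored]
    if not closed:
        raise UndefinedRateError("no closed episodes in record")
    tau = math.comb(record.n, 3) if scale_to_triads else 1

    # successor configuration of each closed episode (next episode of the triad)
    by_triad: dict[tuple[str, str, str], list[TriadEpisode]] = {}
    for e in eps:
        by_triad.setdefault(e.triad, []).append(e)

    int_trials = int_conv = 0
    tr_trials = tr_to_int = 0
    for tri, seq in by_triad.items():
        seq.sort(key=lambda e: e.start_event_index)
        for k, e in enumerate(seq):
            if e.configuration is TriadConfiguration.INTRANSITIVE:
                int_trials += e.duration_interactions
                if not e.censored:
                    int_conv += 1
            else:
                tr_trials += e.duration_interactions
                if not e.censored:
                    succ = seq[k + 1]
                    if succ.configuration is TriadConfiguration.INTRANSITIVE:
                        tr_to_int += 1

    alpha_defined = int_trials > 0
    beta_defined = tr_trials > 0
    alpha_hat = tau * int_conv / int_trials if alpha_defined else float("nan")
    beta_hat = tau * tr_to_int / tr_trials if beta_defined else float("nan")
    alpha_ci = (
        tuple(tau * v for v in _clopper_pearson(int_conv, int_trials, confidence))
        if alpha_defined
        else (float("nan"), float("nan"))
    )
    beta_ci = (
        tuple(tau * v for v in _clopper_pearson(tr_to_int, tr_trials, confidence))
        if beta_defined
        else (float("nan"), float("nan"))
    )
    return RateEstimates(
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        alpha_ci=alpha_ci,  # type: ignore[arg-type]
        beta_ci=beta_ci,  # type: ignore[arg-type]
        alpha_defined=alpha_defined,
        beta_defined=beta_defined,
        n_intransitive_trials=int_trials,
        n_intransitive_conversions=int_conv,
        n_transitive_trials=tr_trials,
        n_transitive_to_intransitive=tr_to_int,
        tau_scale=float(tau),
    )


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_record(record: InteractionRecord, order: Sequence[str] | None = None, ax=None):
    """Music-notation display of a record.

    Individuals are horizontal lines (top = highest final rank), each
    attack a vertical arrow from aggressor to recipient at its time.
    """
    import matplotlib.pyplot as plt

    if order is None:
        rel, _ = dominance_relations(attack_matrix(record))
        order = rank_order(rel, record.roster).order
    ypos = {name: len(order) - i for i, name in enumerate(order)}
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2 + 0.5 * len(order)))
    tmax = record.events[-1].time_s if record.events else 1.0
    for name, y in ypos.items():
        ax.hlines(y, 0, tmax / 60.0, color="0.6", lw=1)
        ax.text(-0.01 * tmax / 60.0, y, name, ha="right", va="center")
    for ev in record.events:
        x = ev.time_s / 60.0
        ax.annotate(
            "",
            xy=(x, ypos[ev.recipient]),
            xytext=(x, ypos[ev.actor]),
            arrowprops=dict(arrowstyle="->", lw=0.8, color="C0"),
        )
    ax.set_xlabel("time (min)")
    ax.set_yticks([])
    ax.set_xlim(left=-0.05 * tmax / 60.0)
    return ax
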