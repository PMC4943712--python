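"""Markov-chain simulation of the two interaction rules on tournaments.

The model: a group of ``n`` animals holds a complete tournament of
dominance directions (Rule 1).  At each step one triad is selected
uniformly at random and a uniform variate ``y`` is drawn.  If the triad is
intransitive and ``y <= alpha``, one of its three edges (chosen uniformly)
is reversed — any such reversal makes the triad transitive.  If the triad
is transitive and ``y <= beta``, the unique destabilizing counterattack
(bottom animal attacks the dominant one) is applied, making it a 3-cycle.
Otherwise nothing changes.  ``alpha = P(I -> T)`` and ``beta = P(T -> I)``
are the two conversion probabilities; Rule 2 is the regime ``beta << alpha``.

The observable is the long-run fraction of observations at which the whole
tournament is transitive (the hierarchy linear), written P(T).  For n = 3
the linearity indicator is itself a two-state Markov chain and the
stationary law is P(T) = alpha / (alpha + beta); for larger n, P(T) still
depends on (alpha, beta) only through that ratio, but the functional form
is not known in closed form.

Protocol defaults follow the original study: each replicate runs
``1000 * tau`` steps from a fresh uniform random tournament, and
``1000 * tau`` replicates are pooled (``tau = C(n, 3)``).

Implementation notes: replicate r of a run with master seed s derives four
independent child streams from ``SeedSequence(s, spawn_key=(r,))`` — initial
tournament, triad indices, y variates, and edge choices (the edge stream is
consumed only when an alpha-conversion fires).  The hot loop is a numba
kernel that tracks the number of intransitive triads incrementally (only
the n - 2 triads through a flipped pair can change label); the pure-Python
``simulate_step`` is the reference implementation and the two are
cross-checked bit-for-bit in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .tournament import (
    Tournament,
    TriadConfiguration,
    classify_triad,
    flip_edge,
    p_linear_random,
    random_tournament,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_step",
    "run_chain",
    "estimate_p_linear",
    "analytic_p_linear_triad",
    "sweep_ratio",
    "table1_grid",
    "table1_deviation",
    "TABLE1_PROBABILITIES",
]

#: The 5x5 probability grid of the three-animal experiment.
TABLE1_PROBABILITIES: tuple[float, ...] = (0.0, 0.1, 0.5, 0.9, 1.0)


def _check_probability(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one Monte-Carlo experiment.

    ``steps_per_sim`` and ``n_sims`` default to the protocol value
    ``1000 * tau`` when left as None.  ``observe_initial`` controls whether
    the initial tournament's linearity is counted among the observations
    (states t = 0..steps) or only post-step states (t = 1..steps).
    """

    n: int
    alpha: float
    beta: float
    steps_per_sim: int | None = None
    n_sims: int | None = None
    seed: int = 0
    observe_initial: bool = True

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got n={self.n}")
        _check_probability("alpha", self.alpha)
        _check_probability("beta", self.beta)
        if self.steps_per_sim is not None and self.steps_per_sim < 1:
            raise ValueError("steps_per_sim must be >= 1")
        if self.n_sims is not None and self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")

    @property
    def tau(self) -> int:
        return math.comb(self.n, 3)

    @property
    def resolved_steps(self) -> int:
        return self.steps_per_sim if self.steps_per_sim is not None else 1000 * max(self.tau, 1)

    @property
    def resolved_sims(self) -> int:
        return self.n_sims if self.n_sims is not None else 1000 * max(self.tau, 1)


@dataclass(frozen=True)
class SimulationResult:
    """Pooled estimate of P(T) with its Monte-Carlo standard error.

    ``p_linear`` is the unweighted mean of the per-replicate linear
    fractions (identical to the pooled fraction since replicates have equal
    length); the standard error comes from the between-replicate variance.
    """

    p_linear: float
    n_observations: int
    per_sim_fractions: np.ndarray
    mc_standard_error: float
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _is_cyclic(adj, a, b, c):
    return (adj[a, b] == 1 and adj[b, c] == 1 and adj[c, a] == 1) or (
        adj[b, a] == 1 and adj[c, b] == 1 and adj[a, c] == 1
    )


@njit(cache=False)
def _flip_and_delta(adj, i, j):
    """Flip pair {i, j} in place; return the change in the cyclic count."""
    n = adj.shape[0]
    delta = 0
    for k in range(n):
        if k != i and k != j:
            if _is_cyclic(adj, i, j, k):
                delta -= 1
    adj[i, j], adj[j, i] = adj[j, i], adj[i, j]
    for k in range(n):
        if k != i and k != j:
            if _is_cyclic(adj, i, j, k):
                delta += 1
    return delta


@njit(cache=False)
def _count_cyclic(adj, triads):
    c = 0
    for t in range(triads.shape[0]):
        if _is_cyclic(adj, triads[t, 0], triads[t, 1], triads[t, 2]):
            c += 1
    return c


@njit(cache=False)
def _chain_kernel(adj, triads, triad_idx, ys, edge_choices, alpha, beta, out):
    """Evolve one replicate; fill ``out`` with linearity at t = 0..steps.

    ``adj`` is modified in place.  Returns the number of edge-choice
    variates consumed (the edge stream advances only on alpha-conversions).
    """
    steps = triad_idx.shape[0]
    c = _count_cyclic(adj, triads)
    out[0] = 1 if c == 0 else 0
    ep = 0
    for s in range(steps):
        ti = triad_idx[s]
        a = triads[ti, 0]
        b = triads[ti, 1]
        d = triads[ti, 2]
        y = ys[s]
        if _is_cyclic(adj, a, b, d):
            if y <= alpha:
                e = edge_choices[ep]
                ep += 1
                if e == 0:
                    i, j = a, b
                elif e == 1:
                    i, j = a, d
                else:
                    i, j = b, d
                c += _flip_and_delta(adj, i, j)
        else:
            if y <= beta:
                # the unique destabilizing move: flip dominant -> bottom
                sa = adj[a, b] + adj[a, d]
                sb = adj[b, a] + adj[b, d]
                if sa == 2:
                    i = a
                elif sb == 2:
                    i = b
                else:
                    i = d
                if sa == 0:
                    j = a
                elif sb == 0:
                    j = b
                else:
                    j = d
                c += _flip_and_delta(adj, i, j)
        out[s + 1] = 1 if c == 0 else 0
    return ep


# ---------------------------------------------------------------------------
# replicate stream plumbing
# ---------------------------------------------------------------------------

def _replicate_rngs(seed: int, replicate: int):
    """Four independent child streams for one replicate.

    Order: initial tournament, triad indices, y variates, edge choices.
    """
    root = np.random.SeedSequence(entropy=seed, spawn_key=(replicate,))
    children = root.spawn(4)
    return tuple(np.random.default_rng(c) for c in children)


def _draw_replicate(config: SimulationConfig, replicate: int):
    steps = config.resolved_steps
    tau = max(config.tau, 1)
    init_rng, triad_rng, y_rng, edge_rng = _replicate_rngs(config.seed, replicate)
    t0 = random_tournament(config.n, init_rng)
    triad_idx = triad_rng.integers(0, tau, size=steps)
    ys = y_rng.random(steps)
    edges = edge_rng.integers(0, 3, size=steps)
    return t0, triad_idx, ys, edges


def _triad_array(n: int) -> np.ndarray:
    tri = list(itertools.combinations(range(n), 3))
    if not tri:  # n = 2: no triads; use a dummy row never selected
        return np.zeros((0, 3), dtype=np.int64)
    return np.array(tri, dtype=np.int64)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_step(
    t: Tournament,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
) -> tuple[Tournament, bool]:
    """One step of the Rule-2 Markov process (reference implementation).

    Draw order: triad index, then y, then (only when an alpha-conversion
    fires) the edge choice.  Returns the new tournament and whether an edge
    was reversed.  Rule 1 (completeness) holds on the output.
    """
    _check_probability("alpha", alpha)
    _check_probability("beta", beta)
    triads = t.triads()
    if not triads:
        return t, False
    tri = triads[int(rng.integers(len(triads)))]
    y = float(rng.random())
    a, b, c = tri
    if classify_triad(t, tri) is TriadConfiguration.INTRANSITIVE:
        if y <= alpha:
            e = int(rng.integers(3))
            pair = ((a, b), (a, c), (b, c))[e]
            return flip_edge(t, pair), True
    else:
        if y <= beta:
            adj = t._adj
            wins = {v: int(adj[v, u] + adj[v, w]) for v, u, w in ((a, b, c), (b, a, c), (c, a, b))}
            dominant = max(tri, key=lambda v: wins[v])
            bottom = min(tri, key=lambda v: wins[v])
            return flip_edge(t, (dominant, bottom)), True
    return t, False


def run_chain(
    config: SimulationConfig, replicate: int = 0
) -> np.ndarray:
    """Linearity indicator stream of one replicate chain.

    Returns a boolean array over the observed states: t = 0..steps when
    ``observe_initial`` (length steps + 1), else t = 1..steps.
    """
    t0, triad_idx, ys, edges = _draw_replicate(config, replicate)
    triads = _triad_array(config.n)
    out = np.zeros(config.resolved_steps + 1, dtype=np.uint8)
    if triads.shape[0] == 0:
        out[:] = 1  # n = 2 is always linear and has no triads to select
    else:
        _chain_kernel(
            t0._adj, triads, triad_idx, ys, edges, config.alpha, config.beta, out
        )
    indicators = out.astype(bool)
    return indicators if config.observe_initial else indicators[1:]


def estimate_p_linear(config: SimulationConfig) -> SimulationResult:
    """Estimate P(T): pool linearity indicators over independent replicates.

    Each replicate starts from a fresh uniform random tournament and runs
    ``steps_per_sim`` steps.  Each replicate contributes ``steps_per_sim``
    observations: the states *before* each step (t = 0..steps-1) when
    ``observe_initial`` (default), else the states after each step
    (t = 1..steps).  The estimate is the mean per-replicate linear
    fraction with a between-replicate standard error.
    """
    n_sims = config.resolved_sims
    steps = config.resolved_steps
    triads = _triad_array(config.n)
    obs_len = steps
    fractions = np.empty(n_sims)
    out = np.zeros(steps + 1, dtype=np.uint8)
    for r in range(n_sims):
        t0, triad_idx, ys, edges = _draw_replicate(config, r)
        if triads.shape[0] == 0:
            out[:] = 1
        else:
            _chain_kernel(
                t0._adj, triads, triad_idx, ys, edges, config.alpha, config.beta, out
            )
        window = out[:steps] if config.observe_initial else out[1:]
        fractions[r] = window.mean()
    p = float(fractions.mean())
    se = float(fractions.std(ddof=1) / math.sqrt(n_sims)) if n_sims > 1 else float("nan")
    return SimulationResult(
        p_linear=p,
        n_observations=n_sims * obs_len,
        per_sim_fractions=fractions,
        mc_standard_error=se,
        config=config,
    )


def analytic_p_linear_triad(alpha: float, beta: float) -> float:
    """Stationary P(T) for three animals.

    For alpha, beta > 0 the linearity indicator is a two-state chain with
    stationary linear probability ``alpha / (alpha + beta)``.  If both are
    zero the chain is frozen and P(T) equals the random-tournament value
    3!/2**3 = 0.75.  If exactly one is zero the returned value (0 or 1) is
    the long-run limit of an absorbing chain, approached only as the number
    of steps grows.
    """
    _check_probability("alpha", alpha)
    _check_probability("beta", beta)
    if alpha == 0.0 and beta == 0.0:
        return p_linear_random(3)
    return alpha / (alpha + beta)


def table1_grid() -> list[tuple[float, float]]:
    """The 25 (alpha, beta) cells of the three-animal grid, row-major in beta."""
    return [(a, b) for b in TABLE1_PROBABILITIES for a in TABLE1_PROBABILITIES]


def sweep_ratio(
    n: int,
    grid: Sequence[tuple[float, float]],
    *,
    seed: int = 0,
    steps_per_sim: int | None = None,
    n_sims: int | None = None,
    observe_initial: bool = True,
) -> pd.DataFrame:
    """Estimate P(T) over an (alpha, beta) grid.

    One row per cell with the ratio alpha/(alpha+beta) (NaN and flagged
    when alpha = beta = 0), the estimate, its Monte-Carlo standard error,
    the number of pooled observations, and the cell's derived seed.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty (alpha, beta) grid")
    rows = []
    for idx, (alpha, beta) in enumerate(grid):
        cell_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(idx,)).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        cfg = SimulationConfig(
            n=n,
            alpha=alpha,
            beta=beta,
            steps_per_sim=steps_per_sim,
            n_sims=n_sims,
            seed=cell_seed,
            observe_initial=observe_initial,
        )
        res = estimate_p_linear(cfg)
        ratio = float("nan") if alpha == 0 and beta == 0 else alpha / (alpha + beta)
        rows.append(
            {
                "n": n,
                "alpha": alpha,
                "beta": beta,
                "ratio": ratio,
                "ratio_defined": not (alpha == 0 and beta == 0),
                "p_linear": res.p_linear,
                "mc_se": res.mc_standard_error,
                "n_obs": res.n_observations,
                "seed": cell_seed,
            }
        )
    return pd.DataFrame(rows)


def table1_deviation(
    steps_multiplier: int = 1,
    *,
    n_sims: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Finite-sampling error of the three-animal grid against the analytic law.

    Runs the 25-cell grid with ``1000 * steps_multiplier`` steps per
    replicate and returns per-cell absolute deviations (percentage points)
    from the analytic stationary value, plus the maximum deviation over the
    24 cells excluding alpha = beta = 0 (whose analytic value is the frozen
    random-tournament probability and is reported in the table only).
    """
    if steps_multiplier < 1:
        raise ValueError("steps_multiplier must be >= 1")
    df = sweep_ratio(
        3,
        table1_grid(),
        seed=seed,
        steps_per_sim=1000 * steps_multiplier,
        n_sims=n_sims if n_sims is not None else 1000,
    )
    analytic = [
        analytic_p_linear_triad(a, b) for a, b in zip(df["alpha"], df["beta"])
    ]
    df = df.assign(
        analytic=analytic,
        deviation_pp=(df["p_linear"] - np.asarray(analytic)).abs() * 100.0,
    )
    mask = ~((df["alpha"] == 0) & (df["beta"] == 0))
    max_dev = float(df.loc[mask, "deviation_pp"].max())
    return df, max_dev
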