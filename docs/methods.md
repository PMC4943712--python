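# Methods

## Model

The package simulates dominance-hierarchy dynamics as a Markov chain on
tournament graphs.  A group of n animals carries a complete orientation of
all n(n−1)/2 pairs (each edge is the most recent attack direction; Rule 1
keeps the orientation complete at all times).  Each of the τ = C(n, 3)
triads is transitive or a 3-cycle, and the chain's update is purely
triadic: select a triad uniformly, draw y ~ U(0, 1), and

* if the triad is intransitive and y ≤ α, reverse one of its three edges
  (uniform choice; every choice produces a transitive triad);
* if the triad is transitive and y ≤ β, apply the unique destabilising
  move — reverse the dominant→bottom edge, producing a 3-cycle;
* otherwise leave the tournament unchanged.

The comparison y ≤ α (resp. β) uses the inclusive inequality; with y drawn
from [0, 1) the fire probability is exactly α up to one part in 2⁵³, and
α = 0 or β = 0 freezes the corresponding conversion for all practical
purposes.

Assumptions worth stating: triads are selected with replacement and
uniformly (no activity differences between individuals); conversions are
memoryless (no winner/loser effects, no prior attributes — these are the
alternative model families the triadic dynamics are contrasted with); and
the state space is the finite set of 2^(n(n−1)/2) tournaments, so for
α, β > 0 the chain is ergodic.

## Estimator and protocol

P(T) is the long-run fraction of observations at which the tournament has
no intransitive triad (equivalently: its score sequence is a permutation
of 0..n−1).  The default protocol runs 1000·τ independent replicates of
1000·τ steps, each from a fresh uniform random tournament — deliberately a
*harder* initial condition than real groups, which form fewer cycles than
chance.  Each replicate contributes its per-replicate linear fraction; the
estimate is their unweighted mean (identical to the pooled fraction, since
replicates have equal length) and the reported standard error comes from
the between-replicate variance, which correctly absorbs the within-chain
autocorrelation.

Observations are the states *before* each step, t = 0 .. steps−1
(`observe_initial=True`, the default; the alternative t = 1 .. steps is
exposed).  Two cells of the three-animal grid are sensitive to this
convention and both favour it: the absorbing cell (α = 0, β = 0.1), whose
expected linear fraction is the geometric-decay average
0.75·(1/β)/steps ≈ 0.75%, matches the published transient value only when
the initial state is counted; and the deterministic oscillation at
α = β = 1 (linearity alternates every step) averages to exactly ½ over an
even number of observations starting at t = 0.

Analytic anchors: the probability that a uniform random tournament is
linear is n!/2^C(n,2); for n = 3 the linearity indicator is itself a
two-state chain with stationary value α/(α+β) (with the random-tournament
value 3!/2³ = 0.75 taken over when α = β = 0, and the absorbing limits 0
and 1 when exactly one rate is zero); for every n the estimated P(T)
depends on (α, β) only through α/(α+β), a property the test suite checks
by ratio-matched comparison at n = 4.

## Randomness and reproducibility

Replicate r of a run with master seed s draws from four child streams of
`numpy.random.SeedSequence(s, spawn_key=(r,))`: initial tournament, triad
indices, y variates, and edge choices (the last consumed only when an
α-conversion fires).  Replicates are therefore mutually independent and
order-independent, runs are bit-reproducible, and the vectorised kernel
and the stepwise reference implementation consume identical draws — a
property asserted in the tests.  Grid sweeps derive one child seed per
cell the same way.  The hot loop is a numba kernel over the adjacency
matrix; it tracks the number of intransitive triads incrementally (an edge
flip can only relabel the n−2 triads through that edge, an O(n) update),
which is what makes the 2.4·10⁸-step analytic-agreement grid run in
seconds.  The pure-Python `simulate_step` remains the audited reference
path.

## Record analysis

Event logs are TSVs (`time_s`, `actor`, `recipient`); timestamps must be
non-decreasing, ties resolved by file order (a counterattack logged after
an attack at the same second is the more recent act), and self-attacks are
rejected with their line number.  The dynamic tournament at any point is
the map pair → most recent direction; it is *partial* until every pair has
interacted.

A triad's first **episode** opens at the event completing its third pair;
an episode closes at the first later event reversing any of its three
directions, which simultaneously opens the next episode; the last episode
of each triad is censored at the record's end.  Durations are measured
both in seconds and in interactions; the interaction count is group-wide
by default (all events strictly after the opening event up to and
including the closing one), with a triad-internal alternative
(`interactions="triad"`) since observational studies can reasonably count
either way.  Censored episodes are tallied separately and excluded from
means and medians: their durations are lower bounds.

The static abstraction chain follows standard ethological practice:
attack counts in a half-open time window [start, end) → pairwise dominance
by strict majority (ties and silent pairs flagged undetermined; a stricter
share threshold is available) → individuals ranked by number dominated,
with the hierarchy flagged linear only when relations are complete and the
scores are distinct.

**Rate estimation.**  Every group event during an episode is one Bernoulli
opportunity for that triad to convert.  The per-event conversion frequency
(closed intransitive episodes ÷ interactions at risk; transitive→
intransitive closures ÷ interactions at risk) estimates α/τ and β/τ, since
the generator selects a given triad with probability 1/τ per event; the
returned estimates are scaled by τ (`scale_to_triads=True`) so they target
(α, β) directly, with Clopper-Pearson 95% intervals scaled the same way.
For n = 3 (τ = 1) the estimator is exact; for n > 3 an episode can also be
terminated by a conversion in an *overlapping* triad flipping a shared
edge, which inflates the estimates somewhat — the coverage property is
therefore asserted at n = 3, and larger-group estimates should be read as
upper bounds.

## Synthetic records

The generator emits the event stream the model implies.  Phase 1 (fill-in)
realises Rule 1: one attack per pair, fair-coin direction, pair order
randomly permuted by default, so the group carries a uniform random
complete tournament after n(n−1)/2 events.  Phase 2 runs the Markov chain,
emitting exactly one observable attack per step: the reversing attack when
a conversion fires, otherwise a repeat attack along a uniformly chosen
existing edge of the selected triad.  Inter-event times are i.i.d.
exponential with a 150 s default mean — the order of magnitude of attack
rates in small hen groups (a handful of pecks per ten minutes).

What the generator does **not** emulate: early counterattack bursts and
other non-stationary features of real records, time-of-day structure,
individual differences in attack rates, session boundaries, and
observation gaps.  Passing tests therefore demonstrate that the analysis
recovers the dynamics *of the model*, not that real animals follow it;
the package's episode statistics are the instrument with which such data
could be assessed once collected.

## Problem sizes and numerical choices

Defaults follow the full published protocol (1000·τ × 1000·τ) wherever it
is cheap: all six three-animal grid checks run it exactly (10⁶
observations per cell).  The larger-group working points use 200
replicates (n = 5: 2000·τ steps; n = 7: 1000·τ steps), giving Monte-Carlo
standard errors near 0.1 pp — comfortably inside the ±1–1.5 pp bands those
points are checked against.  The analytic-agreement statistic is the
maximum absolute deviation of the 24 non-frozen grid cells from α/(α+β)
at 1000 replicates × 10,000 steps; its expected value is dominated by the
absorbing (α = 0, β = 0.1) cell, ≈ 0.75·(1/β)/steps.  Property tests use
smaller sizes chosen so the asserted effect exceeds ~3 standard errors.

Degenerate inputs: n = 2 has no triads — chains are frozen and always
linear; rosters smaller than 3 yield no episodes; an empty event file is
rejected as such; rate estimation on a record with no closed episode
raises rather than returning 0/0.

## Known limitations

* No closed form for P(T) as a function of α/(α+β) is implemented for
  n > 3; the dependence is measured, not derived.
* Supported group sizes are 2–12; the simulation protocol was validated
  against published values for n = 3–7.
* The (α, β) estimator's exactness is limited to n = 3 as described above.
* Multi-session records (e.g. separate observation days) should be split
  with `split_sessions` before episode extraction — configurations during
  unobserved gaps are unknown, so episodes must not span a boundary;
  analysing the parent record whole is the explicit concatenation
  alternative.  The episode extractor itself does not cut at session
  windows.
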