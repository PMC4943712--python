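# peckorder

Dynamics of dominance-hierarchy (pecking-order) formation in small animal
groups: a Markov-chain simulator of two interaction rules on tournament
graphs, together with tools for analysing — and synthesising — timestamped
records of dyadic aggression.

## The model

In small groups (hens, cichlids, and many other species) aggressive
interactions between every pair of animals define a *tournament graph*:
one directed edge per pair, pointing along the most recent attack.  Each
3-subset of animals (a *triad*) is either **transitive** (A ⇒ B, B ⇒ C,
A ⇒ C) or **intransitive** (the 3-cycle A ⇒ B, B ⇒ C, C ⇒ A).  The
hierarchy is **linear** exactly when no triad is intransitive, i.e. the
animals can be ranked by the number of others each dominates.

Two rules are hypothesised to govern the dynamics:

1. **Rule 1** — every pair of animals interacts, so the dominance network
   is always a complete tournament;
2. **Rule 2** — intransitive triads convert to transitive ones at a much
   higher rate than the reverse.

The simulator implements this as a Markov chain.  With τ = C(n, 3) triads,
each step selects one triad uniformly and draws y ~ U(0, 1):

* an intransitive triad converts if y ≤ α = P(I → T), by reversing one of
  its three edges chosen uniformly (any choice yields a transitive triad);
* a transitive triad converts if y ≤ β = P(T → I), via the unique
  destabilising counterattack (the bottom animal attacks the dominant one).

The observable is **P(T)**, the long-run fraction of observations at which
the whole tournament is transitive.  Key analytic facts, all reproduced by
the package:

* a uniform random tournament is linear with probability n! / 2^(n(n−1)/2);
* for n = 3 the linearity indicator is a two-state chain with stationary
  law P(T) = α / (α + β);
* for every n, P(T) depends on (α, β) only through the ratio α / (α + β),
  and achieving mostly-linear hierarchies in larger groups requires β ≪ α —
  e.g. at α = 0.95, groups of five need β = 0.008 to reach P(T) ≈ 90.5%,
  groups of seven β = 0.002 for P(T) ≈ 90.9%.

The record-analysis layer applies the same triad lens to raw event logs
(TSV: `time_s`, `actor`, `recipient`): it tracks the dynamic most-recent
attack tournament, extracts per-triad configuration *episodes* with
durations in interactions and in seconds, counts linear/non-linear
switches, builds windowed attack matrices → dominance relations → rank
orders, and estimates (α, β) with Clopper-Pearson intervals.  Because no
raw hen data are publicly deposited, a synthetic generator emits event
streams with exactly the model's structure (all-pairs fill-in, then
one observable attack per Markov step) for end-to-end validation with
known ground truth.

## Worked example

```python
from peckorder import SimulationConfig, estimate_p_linear

res = estimate_p_linear(SimulationConfig(n=3, alpha=0.9, beta=0.1, seed=0))
print(f"P(T) = {100 * res.p_linear:.2f}% +/- {100 * res.mc_standard_error:.2f} pp")
```

prints `P(T) = 90.01% +/- 0.03 pp` — the default protocol (1,000τ
replicates × 1,000τ steps from fresh random tournaments) landing on the
n = 3 stationary value α/(α+β) = 0.9.

Analysing a synthetic record generated in the Rule-2 regime:

```python
from peckorder import (GeneratorConfig, generate_record, episodes,
                       episode_summary, estimate_rates)

rec = generate_record(GeneratorConfig(n=3, alpha=0.9, beta=0.05,
                                      n_events=5000, seed=0))
summ = episode_summary(episodes(rec))
print(summ.by_configuration[["n_closed", "mean_interactions", "median_seconds"]])
est = estimate_rates(rec)
print(f"alpha_hat = {est.alpha_hat:.3f}  beta_hat = {est.beta_hat:.4f}")
```

```
               n_closed  mean_interactions  median_seconds
configuration
transitive          246              19.17         1975.52
intransitive        246               1.12          117.03
alpha_hat = 0.891  beta_hat = 0.0521
```

Intransitive spells are an order of magnitude shorter than transitive
ones (mean-duration ratio 17.1 here) — the dynamical signature of Rule 2 —
and the episode-based estimator recovers the generating (α, β) = (0.9, 0.05)
within its confidence intervals.

The same workflows are available from the shell:

```sh
peckorder simulate -n 3 --alpha 0.9 --beta 0.1 --seed 0 --out run/
peckorder sweep --table1 -n 3 --seed 0 --out sweep/ --plot sweep/pt.svg
peckorder generate -n 4 --alpha 0.9 --beta 0.05 --events 2000 --seed 0 --out ev.tsv
peckorder analyze ev.tsv --out analysis/
```

Every command writes a JSON run manifest (resolved config, seed, package
version, outputs, timestamps) for exact replay.

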