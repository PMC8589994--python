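# Methods

## Model

`tempassort` simulates a population of `N` zero-intelligence agents on the
nodes of an undirected graph. Each agent carries an evolvable joint strategy
`(behavior, slot)`: an unconditional one-shot prisoner's dilemma move
(always cooperate, `C`, or always defect, `D`) and a single *time slot*
`slot ∈ {1, …, t}` at which the agent implements that move within a
generation. Two agents play one PD game per generation **iff** they share a
graph edge *and* the same slot. Payoffs follow the donation game with
benefit `b` and cost `c`:

|            | partner C | partner D |
|------------|-----------|-----------|
| **self C** | `b − c`   | `−c`      |
| **self D** | `b`       | `0`       |

Payoffs accumulate additively over all same-slot neighbours (each same-slot
pair plays exactly once per generation) and are recomputed from scratch each
generation. An agent with no same-slot neighbour scores 0: no interaction
means no game, never a sucker payoff.

The interest of the model is *temporal assortment*: with `t > 1`, selection
on the slot choice lets cooperators cluster in time as well as space. A
useful diagnostic is the effective degree `k* ≥ k/t`, the realized mean
number of co-active neighbours; the canonical condition for cooperation on
graphs, `b/c > k`, then relaxes to `b/c > k*`, which is why even small `b`
can sustain cooperation once several slots exist.

## Topologies

* **Lattice** — an `m × m` torus (`N = m²`) with von Neumann adjacency:
  every agent has exactly `k = 4` neighbours and there are no boundary
  effects. The periodic boundary is a design choice: it is the only
  boundary under which "every agent has 4 connections" holds exactly.
* **Small world** — a ring substrate with mean degree `k`, each substrate
  edge independently rewired with probability `Pr` (single-endpoint
  Watts–Strogatz rewiring; the edge is kept when no legal target exists;
  disconnection is permitted — isolated agents score 0 and are skipped by
  neighbour-sampling rules). For odd `k` the substrate is the even ring of
  degree `k − 1` plus `⌊N/2⌋` uniformly chosen extra chords, giving mean
  degree `k − (N mod 2)/N`; `k` is a *mean*-degree parameter, so exact
  regularity is not required. Edge count is invariant under rewiring.

## Evolutionary regimes

A *generation* is one payoff computation followed by one update event of the
configured regime — a 2 × 2 design:

* **Transition rule**
  * *Fitness-proportional selection* (death-birth): a uniformly chosen
    agent dies; its graph neighbours compete for the vacant site with
    probability proportional to `max(payoff, 0)`, and the winner's full
    `(behavior, slot)` tuple fills the site. If every neighbour's clipped
    payoff is 0 the winner is uniform over the neighbourhood. This is the
    canonical death-birth rule on graphs — the one for which the
    `b/c > k` condition is derived. A *global* pool variant
    (`selection_pool="global"`) is also provided: the replacement strategy
    is drawn from the population-wide, per-strategy clipped payoff sums
    (`strategy_fitness_table`), with a uniform-over-extant-strategies
    fallback when all sums are 0. The neighbour pool is the default: in
    validation it reproduces the published aggregate statistics, while the
    global pool inverts the cooperator/defector fixation balance.
  * *Pairwise comparison*: a focal agent samples one graph neighbour
    uniformly (any slot) and copies its full tuple iff the neighbour's
    payoff is *strictly* higher; ties keep the incumbent.
* **Update dynamic** — *asynchronous*: one event per generation;
  *synchronous*: every node is evaluated against the same pre-update state
  and the population is replaced in one batch.

Strategy *transmission* is purely spatial in all regimes: slots restrict
game play only. Negative payoffs enter selection only through clipping at
0; no Fermi temperature or other smoothing is introduced.

Behavioral **fixation** (all agents sharing one PD move; slots may stay
heterogeneous) is absorbing — there is no mutation — so runs stop at the
first monomorphic census. Generation 0 is the post-initialization census;
a run lasts at most `G = 10000` generations, and "non-convergence" means no
behavioral fixation by generation `G`.

## Initialization and randomness

Populations are seeded uniformly: behavior `~ U{C, D}` and slot
`~ U{1..t}` independently per agent. Each run's single seed drives three
spawned streams (small-world construction, initial seeding, update draws).
The compiled engine draws exclusively via `np.random.random()` on a
per-run-seeded MT19937 stream with a fixed draw order (focal first, then
the neighbour/strategy draw, consumed only when a choice exists), so runs
are bit-reproducible and can be replayed draw-for-draw by the interpreted
reference implementation used in the tests. Sweep replicate seeds derive
from `(base_seed, cell_index, replicate)`, independent of execution order.

## Numerical and degenerate-input choices

* Weighted draws are inverse-CDF on the cumulative weight vector; the
  index is clamped to the last positive-weight entry to guard against
  floating-point boundary overshoot.
* Uniform index picks are `int(r·m)` clamped to `m − 1`.
* Ties in pairwise comparison keep the incumbent (strict inequality).
* Isolated focal/dying agents are skipped (no change, no draw consumed).
* Tiny tori (`m < 3`) collapse parallel edges under deduplication and are
  admitted only as test toys; production lattices require `m ≥ 3`.

## Parameters

| Parameter | Meaning | Default / study grid |
|---|---|---|
| `N` | population size (graph nodes) | {100, 225, 400} |
| `t` | number of time slots | 1–10 |
| `b` | PD benefit | 1–10 |
| `c` | PD cost | 1 |
| `k` | (mean) degree | 4 (lattice); {2, 3, 4} (small world) |
| `Pr` | rewiring probability | {0.05, 0.15} baseline; 0.05 in sensitivity grids |
| `G` | generations per run | 10000 |
| replicates | runs per parameter cell | 7 |

The presets `baseline-lattice`, `baseline-smallworld`,
`sensitivity-lattice` and `sensitivity-smallworld` encode these grids;
sensitivity presets fix `Pr = 0.05` (the baseline shows the rewiring
probability is inconsequential, ~72% cooperator fixation at both values).

## What the generator emulates — and what it does not

All data are produced by the simulator itself under the study conditions
above; there is no external data. The model is deliberately abstract:
agents have no memory, no partner recognition, no conditional strategies,
payoff structure is constant in time, and a strategy names exactly one
slot. Passing tests therefore show that the *mechanism* — temporal
assortment under selection on implementation time — behaves as described
within this idealized world; they say nothing about richer temporal
strategies (slot lists, periodic schedules), adjacent-slot interaction, or
any empirical system.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full study grids at
`G = 10000` with these replication choices (the package's own choices,
balancing Monte-Carlo error against desk-scale runtime): lattice baseline
7 replicates/cell; small-world baseline 2; synchronous fitness-proportional
sensitivity 3–5; pairwise asynchronous sensitivity 3. Single-slice
marginals in the acceptance script (`t = 1`, `t = 10`, `N = 100` slices)
use 21–35 replicates/cell to tighten the slice standard errors. A
percentage over `n` runs carries a binomial standard error of
`√(p(1−p)/n)` — about 1.5–3 points at these scales — which is the right
yardstick for comparing any two replications of the same aggregate.

## Known limitations

* The asynchronous mean-fixation-generation scale grows roughly linearly
  with `N` (one replacement event per generation); at `N = 400` the
  conditional mean cooperator fixation generation (~5700) therefore sits
  well above the mid-`N` values, and 10000 generations truncates slow runs.
* With the neighbour death-birth rule the dying agent does not compete for
  its own site; a retention variant is not implemented.
* Small-world substrates for `k = 2, 3` are sparser and fix cooperators a
  few points more often than `k = 4`; the flatness of the `k`-profile
  reported elsewhere is not reproduced exactly (see the per-`k` marginals
  the acceptance tests compute).
* Sweeps execute serially; per-run seeding is worker-independent, so a
  parallel executor could be added without changing any result.
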