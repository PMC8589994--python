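# tempassort

**Temporal assortment in the spatial prisoner's dilemma.**

`tempassort` is an agent-based simulator for studying how the *timing* of
social behavior shapes the evolution of cooperation. Agents sit on the
nodes of a graph — a toroidal lattice or a Watts–Strogatz small-world
network — and carry an evolvable joint strategy `(behavior, slot)`: an
unconditional one-shot prisoner's dilemma move (cooperate or defect) and
the single time slot, out of `t` discrete slots per generation, at which
they implement it. Only graph neighbours **sharing a slot** interact, with
donation-game payoffs (mutual cooperation `b − c`, unilateral defection
`b` vs `−c`, mutual defection 0). Selection — death-birth
fitness-proportional or pairwise comparison, asynchronous or synchronous —
acts on the whole tuple, so cooperators can escape defectors by assorting
in time as well as space: each agent's *effective* degree is bounded below
by `k* = k/t`, and cooperation spreads when `b/c > k*` even where
`b/c > k` fails.

The package is aimed at researchers in evolutionary game theory and social
evolution who want a fast, seeded, fully reproducible implementation of
this model with its complete parameter-sweep and aggregation pipeline.

## Worked example

One run on a 15 × 15 lattice with five time slots:

```bash
tempassort run --n 225 --t 5 --b 2 --seed 7 --out demo/
```

```json
{"config": {"n": 225, "t": 5, "b": 2.0, "c": 1.0, "graph_kind": "lattice",
  "k": 4, "pr": 0.0, "transition_rule": "fitness_proportional",
  "update": "async", "selection_pool": "neighbor", "generations": 10000,
  "seed": 7, "record_occupancy": false, "occupancy_stride": 10},
 "fixated": true, "fixed_behavior": "C", "fixation_generation": 3310,
 "end_generation": 3310, "final_coop_proportion": 1.0,
 "occupied_slots_final": 4}
```

Cooperators fixed at generation 3310, spread over 4 of the 5 slots — at
`b = 2` on a degree-4 lattice this would not happen without time slots.
The same comparison as a small sweep, from Python:

```python
from tempassort import (preset, run_sweep, fixation_rate, effective_degree)

spec = preset("baseline-lattice", replicates=2, base_seed=42).restrict(
    t_values=(1, 5, 10), b_values=(2.0,))
result = run_sweep(spec)
for t in (1, 5, 10):
    print(f"t={t:2d}  k*={effective_degree(4, t):.1f}  "
          f"cooperator fixation: {fixation_rate(result, {'t': t}):.1f}%")
```

```
t= 1  k*=4.0  cooperator fixation: 0.0%
t= 5  k*=0.8  cooperator fixation: 66.7%
t=10  k*=0.4  cooperator fixation: 83.3%
```

With a single slot (`k* = 4 > b/c = 2`) cooperation never fixes; five or
ten slots push the effective degree below `b/c` and cooperators take over
most runs.

The command line also provides `sweep` (full parameter grids to CSV, with
presets `baseline-lattice`, `baseline-smallworld`, `sensitivity-lattice`,
`sensitivity-smallworld`), `summarize` (fixation / non-convergence rates
and box statistics from a sweep table) and `export-graph` (plain-text edge
lists for reproducibility audits). Every output embeds the fully resolved
configuration and seed, and repeating any command with the same seed
reproduces its output byte for byte.

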