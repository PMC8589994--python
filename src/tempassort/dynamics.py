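"""Evolutionary regimes: {death-birth fitness-proportional, pairwise comparison} x {async, sync}.

A *generation* is one payoff computation (:func:`tempassort.game.compute_payoffs`)
followed by one application of the configured regime. The four regimes are
one-generation state transitions:

* **Fitness-proportional selection** (death-birth): an agent dies and the
  vacant site is filled by a strategy drawn with probability proportional to
  payoff. The default selection pool is the dying agent's graph
  neighbourhood (canonical death-birth updating on graphs: neighbours
  compete for the site proportional to their clipped payoffs). A global,
  strategy-level pool — replacement drawn from
  :func:`strategy_fitness_table` over the whole population — is available
  via ``DynamicsSpec.selection_pool = SelectionPool.GLOBAL``.
* **Pairwise comparison**: a focal agent samples one graph neighbour
  (any slot) and copies its full ``(behavior, slot)`` tuple if and only if
  the neighbour's payoff is strictly higher; ties keep the incumbent.
* **Asynchronous** updating applies one replacement event per generation;
  **synchronous** updating evaluates every node against the pre-update state
  and replaces the population in one batch.

Strategy *transmission* is purely spatial: neighbour sampling and site
competition ignore time slots, which restrict only game play.

Negative payoffs are clipped to 0 before normalisation; when every weight in
the relevant pool is 0 the draw falls back to uniform (over extant
strategies for the global pool, over the neighbourhood for death-birth).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, StructuralError
from .game import Behavior, PayoffParams, PopulationState, Strategy
from .networks import GraphKind, InteractionGraph

__all__ = [
    "TransitionRule",
    "UpdateDynamic",
    "SelectionPool",
    "DynamicsSpec",
    "FitnessTable",
    "strategy_fitness_table",
    "fps_async_step",
    "fps_sync_step",
    "pairwise_async_step",
    "pairwise_sync_step",
    "step",
]


class TransitionRule(str, enum.Enum):
    FITNESS_PROPORTIONAL = "fitness_proportional"
    PAIRWISE = "pairwise"


class UpdateDynamic(str, enum.Enum):
    ASYNC = "async"
    SYNC = "sync"


class SelectionPool(str, enum.Enum):
    """Pool competing for a vacated site under fitness-proportional selection."""

    NEIGHBOR = "neighbor"
    GLOBAL = "global"


#: 2x2 design cells (transition rule x update dynamic), indexed a-d on the
#: lattice and e-h on the small-world graph, used in logs and reports.
_CELL_LETTERS = {
    (TransitionRule.FITNESS_PROPORTIONAL, UpdateDynamic.ASYNC): ("a", "e"),
    (TransitionRule.FITNESS_PROPORTIONAL, UpdateDynamic.SYNC): ("b", "f"),
    (TransitionRule.PAIRWISE, UpdateDynamic.ASYNC): ("c", "g"),
    (TransitionRule.PAIRWISE, UpdateDynamic.SYNC): ("d", "h"),
}


@dataclass(frozen=True)
class DynamicsSpec:
    transition_rule: TransitionRule = TransitionRule.FITNESS_PROPORTIONAL
    update: UpdateDynamic = UpdateDynamic.ASYNC
    selection_pool: SelectionPool = SelectionPool.NEIGHBOR

    def cell_label(self, graph_kind: GraphKind) -> str:
        """Design-cell letter (a-h) for this regime on the given topology."""
        lattice, small_world = _CELL_LETTERS[(self.transition_rule, self.update)]
        return lattice if graph_kind is GraphKind.LATTICE else small_world


@dataclass
class FitnessTable:
    """Per-strategy selection weights over extant strategies.

    ``weights`` maps each strategy with at least one living adopter to
    ``max(0, sum of its adopters' payoffs)``; extinct strategies are absent
    (there is no mutation). When every weight is 0 the table is flagged
    ``degenerate`` and :attr:`probabilities` falls back to uniform over
    extant strategies.
    """

    weights: dict[Strategy, float]
    degenerate: bool = field(init=False)

    def __post_init__(self):
        self.degenerate = all(w == 0.0 for w in self.weights.values())

    @property
    def probabilities(self) -> dict[Strategy, float]:
        if self.degenerate:
            p = 1.0 / len(self.weights)
            return {s: p for s in self.weights}
        total = sum(self.weights.values())
        return {s: w / total for s, w in self.weights.items()}


def strategy_fitness_table(state: PopulationState, t: int) -> FitnessTable:
    """Population-wide payoff sum per extant strategy, clipped at 0.

    Strategies are keyed in engine order: defector strategies by ascending
    slot, then cooperator strategies by ascending slot.
    """
    if state.payoffs is None:
        raise StructuralError("payoffs must be computed before building the fitness table")
    if state.slots.max() > t:
        raise StructuralError("slot id exceeds configured slot count")
    idx = state.behaviors.astype(np.int64) * t + (state.slots - 1)
    sums = np.bincount(idx, weights=state.payoffs, minlength=2 * t)
    counts = np.bincount(idx, minlength=2 * t)
    weights: dict[Strategy, float] = {}
    for s in range(2 * t):
        if counts[s] > 0:
            strat = Strategy(Behavior(s // t), s % t + 1)
            weights[strat] = max(0.0, float(sums[s]))
    return FitnessTable(weights)


def _require(spec: DynamicsSpec, rule: TransitionRule, update: UpdateDynamic) -> None:
    if spec.transition_rule is not rule or spec.update is not update:
        raise ConfigurationError(
            f"step function expects ({rule.value}, {update.value}), got "
            f"({spec.transition_rule.value}, {spec.update.value})")


def _check_state(graph: InteractionGraph, state: PopulationState) -> None:
    if state.n != graph.n_nodes:
        raise StructuralError(
            f"state covers {state.n} nodes but graph has {graph.n_nodes}")
    if state.payoffs is None:
        raise StructuralError("payoffs must be computed before a dynamics step")


def _pick_index(rng: np.random.Generator, m: int) -> int:
    """Uniform index in [0, m) via one uniform double (engine convention)."""
    j = int(rng.random() * m)
    return m - 1 if j == m else j


def _db_replacement(indptr: np.ndarray, indices: np.ndarray,
                    payoffs: np.ndarray, u: int,
                    rng: np.random.Generator) -> int | None:
    """Death-birth winner among ``u``'s neighbours, or None if ``u`` is isolated.

    Neighbours compete proportionally to ``max(payoff, 0)``; if all clipped
    weights are 0 the winner is uniform over the neighbourhood. Consumes
    exactly one uniform draw when a neighbourhood exists.
    """
    lo, hi = indptr[u], indptr[u + 1]
    if hi == lo:
        return None
    nbrs = indices[lo:hi]
    w = np.maximum(payoffs[nbrs], 0.0)
    total = w.sum()
    r = rng.random()
    if total > 0.0:
        j = int(np.searchsorted(np.cumsum(w), r * total, side="right"))
        return int(nbrs[min(j, len(nbrs) - 1)])
    return int(nbrs[min(int(r * len(nbrs)), len(nbrs) - 1)])


def _global_replacement(table: FitnessTable, rng: np.random.Generator) -> Strategy:
    """Draw a strategy from the global fitness table (one uniform consumed)."""
    strategies = list(table.weights)
    if table.degenerate:
        weights = np.ones(len(strategies))
    else:
        weights = np.array([table.weights[s] for s in strategies])
    cum = np.cumsum(weights)
    r = rng.random() * cum[-1]
    return strategies[min(int(np.searchsorted(cum, r, side="right")), len(strategies) - 1)]


def fps_async_step(graph: InteractionGraph, state: PopulationState,
                   params: PayoffParams, spec: DynamicsSpec,
                   rng: np.random.Generator, t: int | None = None) -> PopulationState:
    """One death-birth event: a uniform node dies and its site is refilled.

    The replacement pool (neighbourhood vs global strategy table) follows
    ``spec.selection_pool`` and is evaluated on the pre-death state. All
    other nodes are unchanged. Returns a new state with stale payoffs
    cleared.
    """
    _require(spec, TransitionRule.FITNESS_PROPORTIONAL, UpdateDynamic.ASYNC)
    _check_state(graph, state)
    out = PopulationState(state.behaviors.copy(), state.slots.copy())
    u = _pick_index(rng, state.n)
    if spec.selection_pool is SelectionPool.GLOBAL:
        table = strategy_fitness_table(state, int(state.slots.max()) if t is None else t)
        strat = _global_replacement(table, rng)
        out.behaviors[u] = int(strat.behavior)
        out.slots[u] = strat.slot
    else:
        indptr, indices = graph.csr()
        winner = _db_replacement(indptr, indices, state.payoffs, u, rng)
        if winner is not None:
            out.behaviors[u] = state.behaviors[winner]
            out.slots[u] = state.slots[winner]
    return out


def fps_sync_step(graph: InteractionGraph, state: PopulationState,
                  params: PayoffParams, spec: DynamicsSpec,
                  rng: np.random.Generator, t: int | None = None) -> PopulationState:
    """Synchronous death-birth: every site is refilled in one batch.

    All replacements are evaluated against the same pre-replacement payoffs
    (no intra-generation feedback); nodes are processed in id order, one
    uniform draw per non-isolated node (global pool: one draw per node).
    """
    _require(spec, TransitionRule.FITNESS_PROPORTIONAL, UpdateDynamic.SYNC)
    _check_state(graph, state)
    out = PopulationState(state.behaviors.copy(), state.slots.copy())
    if spec.selection_pool is SelectionPool.GLOBAL:
        table = strategy_fitness_table(state, int(state.slots.max()) if t is None else t)
        for u in range(state.n):
            strat = _global_replacement(table, rng)
            out.behaviors[u] = int(strat.behavior)
            out.slots[u] = strat.slot
    else:
        indptr, indices = graph.csr()
        for u in range(state.n):
            winner = _db_replacement(indptr, indices, state.payoffs, u, rng)
            if winner is not None:
                out.behaviors[u] = state.behaviors[winner]
                out.slots[u] = state.slots[winner]
    return out


def pairwise_async_step(graph: InteractionGraph, state: PopulationState,
                        params: PayoffParams, spec: DynamicsSpec,
                        rng: np.random.Generator) -> PopulationState:
    """One pairwise comparison: focal copies a strictly better sampled neighbour."""
    _require(spec, TransitionRule.PAIRWISE, UpdateDynamic.ASYNC)
    _check_state(graph, state)
    out = PopulationState(state.behaviors.copy(), state.slots.copy())
    indptr, indices = graph.csr()
    u = _pick_index(rng, state.n)
    lo, hi = indptr[u], indptr[u + 1]
    if hi > lo:  # isolated focal nodes are skipped
        v = int(indices[lo + _pick_index(rng, hi - lo)])
        if state.payoffs[v] > state.payoffs[u]:
            out.behaviors[u] = state.behaviors[v]
            out.slots[u] = state.slots[v]
    return out


def pairwise_sync_step(graph: InteractionGraph, state: PopulationState,
                       params: PayoffParams, spec: DynamicsSpec,
                       rng: np.random.Generator) -> PopulationState:
    """Batch pairwise comparison: all adoptions recorded against the current
    state, then applied simultaneously."""
    _require(spec, TransitionRule.PAIRWISE, UpdateDynamic.SYNC)
    _check_state(graph, state)
    out = PopulationState(state.behaviors.copy(), state.slots.copy())
    indptr, indices = graph.csr()
    for u in range(state.n):
        lo, hi = indptr[u], indptr[u + 1]
        if hi > lo:
            v = int(indices[lo + _pick_index(rng, hi - lo)])
            if state.payoffs[v] > state.payoffs[u]:
                out.behaviors[u] = state.behaviors[v]
                out.slots[u] = state.slots[v]
    return out


def step(graph: InteractionGraph, state: PopulationState, params: PayoffParams,
         spec: DynamicsSpec, rng: np.random.Generator,
         t: int | None = None) -> PopulationState:
    """Dispatch one generation step of the configured regime."""
    if spec.transition_rule is TransitionRule.FITNESS_PROPORTIONAL:
        fn = fps_async_step if spec.update is UpdateDynamic.ASYNC else fps_sync_step
        return fn(graph, state, params, spec, rng, t=t)
    fn = (pairwise_async_step if spec.update is UpdateDynamic.ASYNC
          else pairwise_sync_step)
    return fn(graph, state, params, spec, rng)
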