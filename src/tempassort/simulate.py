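"""Single-run execution: initialization, the generation loop, fixation detection.

A *run* evolves one population for up to ``G`` generations (study default
10000) under one combination of topology, payoff parameters, and dynamics
regime. Behavioral fixation — the whole population sharing one PD move,
regardless of slot heterogeneity — is absorbing because no mutation operator
exists, so runs stop early at the first monomorphic census. Generation 0 is
the post-initialization, pre-update census.

All randomness in a run (graph construction, initial seeding, the engine's
update draws) derives from the single ``RunConfig.seed`` through spawned
``numpy`` seed sequences, making a run bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _engine
from .dynamics import DynamicsSpec, SelectionPool, TransitionRule, UpdateDynamic
from .errors import ConfigurationError
from .game import Behavior, PayoffParams, PopulationState
from .networks import GraphKind, InteractionGraph, build_lattice, build_small_world

__all__ = ["RunConfig", "RunResult", "initialize_population", "detect_fixation", "run"]


@dataclass(frozen=True)
class RunConfig:
    """Full specification of one simulation run."""

    n: int = 225
    t: int = 5
    params: PayoffParams = field(default_factory=lambda: PayoffParams(b=2.0, c=1.0))
    graph_kind: GraphKind = GraphKind.LATTICE
    k: int = 4
    pr: float = 0.0
    dynamics: DynamicsSpec = field(default_factory=DynamicsSpec)
    generations: int = 10_000
    seed: int = 0
    record_occupancy: bool = False
    occupancy_stride: int = 10

    def __post_init__(self):
        if self.t < 1:
            raise ConfigurationError(f"slot count must be >= 1, got t={self.t}")
        if self.generations < 1:
            raise ConfigurationError(
                f"generations must be >= 1, got {self.generations}")
        if self.n < 2:
            raise ConfigurationError(f"population size must be >= 2, got n={self.n}")
        if self.occupancy_stride < 1:
            raise ConfigurationError("occupancy_stride must be >= 1")

    def resolved_dict(self) -> dict:
        """Flat JSON-serializable echo of every parameter (audit trail)."""
        return {
            "n": self.n,
            "t": self.t,
            "b": self.params.b,
            "c": self.params.c,
            "graph_kind": self.graph_kind.value,
            "k": self.k,
            "pr": self.pr,
            "transition_rule": self.dynamics.transition_rule.value,
            "update": self.dynamics.update.value,
            "selection_pool": self.dynamics.selection_pool.value,
            "generations": self.generations,
            "seed": self.seed,
            "record_occupancy": self.record_occupancy,
            "occupancy_stride": self.occupancy_stride,
        }


@dataclass
class RunResult:
    """Outcome summary of one run."""

    config: RunConfig
    fixated: bool
    fixed_behavior: Behavior | None
    fixation_generation: int | None
    end_generation: int
    final_coop_proportion: float
    occupied_slots_final: int
    final_state: PopulationState
    occupancy_trajectory: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        return {
            "config": self.config.resolved_dict(),
            "fixated": self.fixated,
            "fixed_behavior": None if self.fixed_behavior is None else self.fixed_behavior.letter,
            "fixation_generation": self.fixation_generation,
            "end_generation": self.end_generation,
            "final_coop_proportion": self.final_coop_proportion,
            "occupied_slots_final": self.occupied_slots_final,
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")

    def write_occupancy_csv(self, path) -> None:
        if self.occupancy_trajectory is None:
            raise ConfigurationError("run was executed without record_occupancy")
        self.occupancy_trajectory.to_csv(path, index=False)


def initialize_population(config: RunConfig, rng: np.random.Generator) -> PopulationState:
    """Uniform random seeding: behavior ~ U{C, D}, slot ~ U{1..t}, independently."""
    behaviors = rng.integers(0, 2, config.n).astype(np.int8)
    slots = rng.integers(1, config.t + 1, config.n)
    return PopulationState(behaviors, slots)


def detect_fixation(state: PopulationState) -> Behavior | None:
    """C or D if the population is behaviorally monomorphic, else None.

    Slot heterogeneity is ignored: fixation is defined on behavior only.
    """
    ncoop = state.n_cooperators
    if ncoop == 0:
        return Behavior.DEFECT
    if ncoop == state.n:
        return Behavior.COOPERATE
    return None


def build_graph(config: RunConfig, seed: int | None = None) -> InteractionGraph:
    if config.graph_kind is GraphKind.LATTICE:
        return build_lattice(config.n)
    return build_small_world(config.n, config.k, config.pr, seed)


def run(config: RunConfig, graph: InteractionGraph | None = None,
        initial_state: PopulationState | None = None) -> RunResult:
    """Execute one run: loop (compute payoffs, one dynamics step) up to G generations.

    Stops early at the first behaviorally monomorphic census (fixation is
    absorbing). When ``graph`` is supplied it is used as-is; otherwise it is
    built from the config (small-world construction consumes a seed derived
    from ``config.seed``). ``initial_state`` replaces the uniform random
    seeding (e.g. to resume a previous run's terminal state); engine draws
    still derive from ``config.seed``.
    """
    graph_ss, init_ss, engine_ss = np.random.SeedSequence(config.seed).spawn(3)
    if graph is None:
        graph = build_graph(config, int(graph_ss.generate_state(1)[0] >> 1))
    elif graph.n_nodes != config.n:
        raise ConfigurationError(
            f"supplied graph has {graph.n_nodes} nodes but config.n={config.n}")

    if initial_state is None:
        state0 = initialize_population(config, np.random.default_rng(init_ss))
    else:
        if initial_state.n != config.n:
            raise ConfigurationError(
                f"initial state has {initial_state.n} agents but config.n={config.n}")
        if initial_state.slots.max() > config.t:
            raise ConfigurationError("initial state uses a slot beyond config.t")
        state0 = initial_state
    behav = state0.behaviors.copy()
    slot0 = (state0.slots - 1).astype(np.int64)

    stride = config.occupancy_stride if config.record_occupancy else 0
    max_rec = (config.generations // stride + 2) if stride else 1
    occ = np.zeros((max_rec, config.t, 2), dtype=np.int64)
    occ_gens = np.zeros(max_rec, dtype=np.int64)

    indptr, indices = graph.csr()
    end_gen, fixated_flag, n_rec = _engine.run_population(
        indptr, indices, behav, slot0,
        config.t, float(config.params.b), float(config.params.c),
        0 if config.dynamics.transition_rule is TransitionRule.FITNESS_PROPORTIONAL else 1,
        0 if config.dynamics.update is UpdateDynamic.ASYNC else 1,
        0 if config.dynamics.selection_pool is SelectionPool.NEIGHBOR else 1,
        config.generations,
        int(engine_ss.generate_state(1)[0] >> 1),
        stride, occ, occ_gens,
    )

    final_state = PopulationState(behav, slot0 + 1)
    fixated = bool(fixated_flag)
    fixed = detect_fixation(final_state) if fixated else None

    trajectory = None
    if stride:
        records = []
        for r in range(n_rec):
            for s in range(config.t):
                records.append((int(occ_gens[r]), s + 1, int(occ[r, s, 0]), int(occ[r, s, 1])))
        trajectory = pd.DataFrame(records, columns=["generation", "slot", "n_coop", "n_def"])

    return RunResult(
        config=config,
        fixated=fixated,
        fixed_behavior=fixed,
        fixation_generation=end_gen if fixated else None,
        end_generation=end_gen,
        final_coop_proportion=final_state.n_cooperators / config.n,
        occupied_slots_final=int(np.unique(final_state.slots).size),
        final_state=final_state,
        occupancy_trajectory=trajectory,
    )
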