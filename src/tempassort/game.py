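"""Strategies and slot-restricted prisoner's dilemma payoffs.

Each agent carries a joint strategy ``(behavior, slot)``: an unconditional
prisoner's dilemma move (always cooperate or always defect) and the single
time slot, out of ``t`` discrete within-generation slots, at which it
implements that move. Two agents play one PD game per generation if and only
if they share a graph edge *and* the same slot. Payoffs follow the standard
donation-game parameterisation: mutual cooperation earns ``b - c`` each, a
unilateral defector earns ``b`` while its exploited partner earns ``-c``,
and mutual defection earns 0.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .errors import ConfigurationError, StructuralError
from .networks import InteractionGraph

__all__ = [
    "Behavior",
    "Strategy",
    "PayoffParams",
    "PopulationState",
    "pair_payoff",
    "compute_payoffs",
    "effective_degree",
]


class Behavior(enum.IntEnum):
    """PD move; the integer codes are the engine's array encoding."""

    DEFECT = 0
    COOPERATE = 1

    @property
    def letter(self) -> str:
        return "C" if self is Behavior.COOPERATE else "D"


class Strategy(NamedTuple):
    """Evolvable tuple: PD behavior plus 1-based time slot."""

    behavior: Behavior
    slot: int


@dataclass(frozen=True)
class PayoffParams:
    """Donation-game payoff parameters: benefit ``b`` and cost ``c``.

    The study regime is integer ``b`` in 1..10 with ``c = 1``; any
    non-negative reals are accepted.
    """

    b: float
    c: float = 1.0

    def __post_init__(self):
        if self.b < 0 or self.c < 0:
            raise ConfigurationError(f"b and c must be non-negative, got b={self.b}, c={self.c}")


@dataclass
class PopulationState:
    """Per-agent strategy assignment, plus payoffs for the current generation.

    ``behaviors`` holds :class:`Behavior` codes (0/1), ``slots`` 1-based slot
    ids. ``payoffs`` is ``None`` until :func:`compute_payoffs` fills it and is
    recomputed from scratch each generation (no carry-over).
    """

    behaviors: np.ndarray
    slots: np.ndarray
    payoffs: np.ndarray | None = None

    def __post_init__(self):
        self.behaviors = np.asarray(self.behaviors, dtype=np.int8)
        self.slots = np.asarray(self.slots, dtype=np.int64)
        if self.behaviors.shape != self.slots.shape or self.behaviors.ndim != 1:
            raise StructuralError("behaviors and slots must be equal-length 1-d arrays")
        if self.behaviors.size == 0:
            raise StructuralError("population must contain at least one agent")
        if not np.isin(self.behaviors, (0, 1)).all():
            raise StructuralError("behaviors must be Behavior codes (0 or 1)")
        if self.slots.min() < 1:
            raise StructuralError("slots are 1-based positive integers")
        if self.payoffs is not None:
            self.payoffs = np.asarray(self.payoffs, dtype=np.float64)
            if self.payoffs.shape != self.behaviors.shape:
                raise StructuralError("payoffs shape mismatch")

    @property
    def n(self) -> int:
        return self.behaviors.size

    @property
    def n_cooperators(self) -> int:
        return int(self.behaviors.sum())

    def strategy(self, node: int) -> Strategy:
        return Strategy(Behavior(int(self.behaviors[node])), int(self.slots[node]))

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.behaviors.copy(), self.slots.copy(),
            None if self.payoffs is None else self.payoffs.copy(),
        )

    # -- CSV round trip (node_id, behavior, slot) --------------------------

    def to_csv(self, path=None) -> str | None:
        buf = io.StringIO()
        buf.write("node_id,behavior,slot\n")
        for i in range(self.n):
            buf.write(f"{i},{Behavior(int(self.behaviors[i])).letter},{int(self.slots[i])}\n")
        text = buf.getvalue()
        if path is None:
            return text
        Path(path).write_text(text)
        return None

    @classmethod
    def from_csv(cls, path) -> "PopulationState":
        lines = Path(path).read_text().splitlines()
        rows = [line.split(",") for line in lines[1:] if line.strip()]
        rows.sort(key=lambda r: int(r[0]))
        behaviors = [1 if r[1].strip() == "C" else 0 for r in rows]
        slots = [int(r[2]) for r in rows]
        return cls(np.array(behaviors), np.array(slots))


def pair_payoff(a: Behavior, b_: Behavior, params: PayoffParams) -> tuple[float, float]:
    """Payoffs of one PD game between moves ``a`` and ``b_``."""
    pa = params.b * int(b_) - params.c * int(a)
    pb = params.b * int(a) - params.c * int(b_)
    return (pa, pb)


def compute_payoffs(graph: InteractionGraph, state: PopulationState,
                    params: PayoffParams) -> PopulationState:
    """One generation of slot-restricted PD play over the whole graph.

    Each node's payoff is the sum of :func:`pair_payoff` outcomes against
    every adjacent node sharing its slot (each such pair plays exactly once).
    Nodes with no same-slot neighbour score 0 — no interaction means no game.
    Returns a new state with ``payoffs`` replaced.
    """
    if state.n != graph.n_nodes:
        raise StructuralError(
            f"state covers {state.n} nodes but graph has {graph.n_nodes}")
    payoffs = np.zeros(state.n, dtype=np.float64)
    if graph.n_edges:
        u, v = graph.edges[:, 0], graph.edges[:, 1]
        same = state.slots[u] == state.slots[v]
        us, vs = u[same], v[same]
        coop = state.behaviors.astype(np.float64)
        np.add.at(payoffs, us, params.b * coop[vs] - params.c * coop[us])
        np.add.at(payoffs, vs, params.b * coop[us] - params.c * coop[vs])
    return PopulationState(state.behaviors.copy(), state.slots.copy(), payoffs)


def effective_degree(k: float, t: int) -> float:
    """Lower bound ``k/t`` on the realized mean same-slot degree.

    With agents spread over ``t`` slots, an agent's *effective* number of
    co-active neighbours is at least ``k/t`` (uniform spreading); uneven slot
    occupancy can only raise it. Reported alongside sweeps for the
    ``b/c > k*`` cooperation diagnostic.
    """
    if t < 1:
        raise ConfigurationError(f"slot count must be >= 1, got {t}")
    return k / t
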