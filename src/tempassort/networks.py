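"""Interaction topologies: toroidal lattice and Watts-Strogatz small-world graphs.

Agents occupy the nodes of an undirected graph; edges define who *can* play
the prisoner's dilemma with whom (actual game play is further restricted to
same-time-slot pairs by :mod:`tempassort.game`).

Two topologies are provided:

* a degree-4 regular lattice — a ``m x m`` grid (``n = m**2``) with von
  Neumann (4-neighbour) adjacency and periodic (toroidal) boundaries, so
  every node has exactly 4 neighbours and there are no edge effects;
* a small-world graph — a ring substrate with mean degree ``k`` whose edges
  are independently rewired with probability ``pr`` (single-endpoint
  Watts-Strogatz rewiring).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, StructuralError

__all__ = [
    "GraphKind",
    "InteractionGraph",
    "build_lattice",
    "build_small_world",
    "read_edgelist",
]


class GraphKind(str, enum.Enum):
    LATTICE = "lattice"
    SMALL_WORLD = "small_world"


def _canonical_edges(pairs) -> np.ndarray:
    """Sort each pair as (min, max) and the list lexicographically."""
    arr = np.asarray(sorted((min(u, v), max(u, v)) for u, v in pairs), dtype=np.int64)
    if arr.size == 0:
        arr = arr.reshape(0, 2)
    return arr


@dataclass
class InteractionGraph:
    """Undirected interaction graph with construction metadata.

    ``edges`` is the canonical edge list: shape ``(E, 2)``, each row
    ``(u, v)`` with ``u < v``, rows lexicographically sorted. Adjacency is
    exposed in CSR form (``indptr`` / ``indices``) for the simulation engine.
    """

    n_nodes: int
    edges: np.ndarray
    graph_kind: GraphKind
    k_param: int
    rewire_prob: float = 0.0
    _indptr: np.ndarray = field(default=None, repr=False, compare=False)
    _indices: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.edges = _canonical_edges(map(tuple, np.asarray(self.edges).reshape(-1, 2)))
        if self.n_nodes < 1:
            raise ConfigurationError(f"n_nodes must be positive, got {self.n_nodes}")
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise StructuralError("edge endpoint outside node range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise StructuralError("self-loop in edge list")
            if len(np.unique(self.edges, axis=0)) != len(self.edges):
                raise StructuralError("duplicate edge in edge list")

    # -- derived structure -------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def degrees(self) -> np.ndarray:
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Adjacency as (indptr, indices); neighbours of ``u`` sorted ascending."""
        if self._indptr is None:
            deg = self.degrees
            indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
            np.cumsum(deg, out=indptr[1:])
            indices = np.empty(2 * self.n_edges, dtype=np.int64)
            fill = indptr[:-1].copy()
            for u, v in self.edges:  # edges sorted => per-node lists sorted
                indices[fill[u]] = v
                fill[u] += 1
            # reverse direction: iterate edges sorted by v then u
            order = np.lexsort((self.edges[:, 0], self.edges[:, 1]))
            for u, v in self.edges[order]:
                indices[fill[v]] = u
                fill[v] += 1
            for u in range(self.n_nodes):  # merge the two sorted blocks
                indices[indptr[u]:indptr[u + 1]].sort()
            self._indptr, self._indices = indptr, indices
        return self._indptr, self._indices

    def neighbors(self, u: int) -> np.ndarray:
        indptr, indices = self.csr()
        return indices[indptr[u]:indptr[u + 1]]

    # -- plain-text export/import (reproducibility audits) -----------------

    def to_edgelist_text(self) -> str:
        return "".join(f"{u} {v}\n" for u, v in self.edges)

    def write_edgelist(self, path) -> None:
        Path(path).write_text(self.to_edgelist_text())


def read_edgelist(path, n_nodes: int, graph_kind: GraphKind = GraphKind.LATTICE,
                  k_param: int = 4, rewire_prob: float = 0.0) -> InteractionGraph:
    """Rebuild an :class:`InteractionGraph` from a plain-text edge list."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            u, v = line.split()
            pairs.append((int(u), int(v)))
    return InteractionGraph(n_nodes, _canonical_edges(pairs), graph_kind,
                            k_param, rewire_prob)


def build_lattice(n: int, seed: int | None = None) -> InteractionGraph:
    """Degree-4 toroidal lattice on ``n = m**2`` nodes.

    Deterministic; ``seed`` is accepted only for interface uniformity with
    :func:`build_small_world`. Node ``(i, j)`` of the grid is id ``i*m + j``
    and is adjacent to its four von Neumann neighbours with periodic
    wrap-around. On degenerate tiny tori (``m < 3``) parallel edges collapse
    under deduplication, leaving degree < 4; production runs use ``m >= 3``.
    """
    m = math.isqrt(n)
    if m * m != n:
        raise ConfigurationError(f"lattice size must be a perfect square, got n={n}")
    pairs = set()
    for i in range(m):
        for j in range(m):
            u = i * m + j
            for di, dj in ((0, 1), (1, 0)):
                v = ((i + di) % m) * m + (j + dj) % m
                if u != v:
                    pairs.add((min(u, v), max(u, v)))
    return InteractionGraph(n, _canonical_edges(pairs), GraphKind.LATTICE, k_param=4)


def build_small_world(n: int, k: int, pr: float, seed: int | None) -> InteractionGraph:
    """Ring-substrate small-world graph with mean degree ``k``.

    Even ``k``: circulant ring where each node links to its ``k/2`` nearest
    neighbours on each side. Odd ``k``: the even ring of degree ``k - 1``
    plus ``n // 2`` extra chords drawn uniformly at random without
    duplication, giving mean degree ``k - (n % 2)/n``. Every substrate edge
    is then independently rewired with probability ``pr``: the edge ``(u, v)``
    is replaced by ``(u, w)`` with ``w`` uniform over nodes that are neither
    ``u`` nor already adjacent to ``u``; if no legal target exists the edge
    is kept. The rewiring scan runs over the canonically sorted substrate
    edge list, so the result is reproducible from ``seed``. Disconnected
    graphs are permitted (isolated agents simply earn payoff 0).
    """
    if not (2 <= k < n):
        raise ConfigurationError(f"small-world degree must satisfy 2 <= k < n, got k={k}, n={n}")
    if not (0.0 <= pr <= 1.0):
        raise ConfigurationError(f"rewiring probability must lie in [0, 1], got {pr}")
    rng = np.random.default_rng(seed)
    pairs: set[tuple[int, int]] = set()
    half = (k - 1) // 2 if k % 2 else k // 2
    for u in range(n):
        for d in range(1, half + 1):
            v = (u + d) % n
            if u != v:
                pairs.add((min(u, v), max(u, v)))
    if k % 2:
        target = len(pairs) + n // 2
        while len(pairs) < target:
            u = int(rng.integers(n))
            v = int(rng.integers(n))
            if u != v and (min(u, v), max(u, v)) not in pairs:
                pairs.add((min(u, v), max(u, v)))

    adjacency = {u: set() for u in range(n)}
    for u, v in pairs:
        adjacency[u].add(v)
        adjacency[v].add(u)
    edges = set(pairs)
    for u, v in sorted(pairs):
        if rng.random() < pr:
            candidates = [w for w in range(n) if w != u and w not in adjacency[u]]
            if candidates:
                w = candidates[int(rng.integers(len(candidates)))]
                edges.discard((u, v))
                adjacency[u].discard(v)
                adjacency[v].discard(u)
                edges.add((min(u, w), max(u, w)))
                adjacency[u].add(w)
                adjacency[w].add(u)
    return InteractionGraph(n, _canonical_edges(edges), GraphKind.SMALL_WORLD,
                            k_param=k, rewire_prob=pr)
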