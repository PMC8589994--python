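"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — explicit Python loops over edges and
nodes — and kept separate from the package's vectorised / compiled paths so
the two can be compared. ``ref_run`` additionally replays the compiled
engine's documented draw sequence (one ``np.random.random()`` per decision,
index picks as ``int(r * m)``) on numpy's legacy global MT19937 stream,
which numba's ``np.random`` matches bit-for-bit; it therefore reproduces an
engine run draw-for-draw. ``enumerate_one_step`` computes exact one-step
successor distributions by exhaustive enumeration for all four regimes.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np


def ref_payoffs(edges, behav, slot, b, c):
    """Brute-force slot-restricted PD payoffs via an explicit edge loop."""
    pay = [0.0] * len(behav)
    for (u, v) in edges:
        if slot[u] == slot[v]:
            pay[u] += b * behav[v] - c * behav[u]
            pay[v] += b * behav[u] - c * behav[v]
    return pay


def ref_payoffs_slotfree(edges, behav, b, c):
    """Slot-free spatial PD payoffs: every edge plays."""
    pay = [0.0] * len(behav)
    for (u, v) in edges:
        pay[u] += b * behav[v] - c * behav[u]
        pay[v] += b * behav[u] - c * behav[v]
    return pay


def _neighbors(edges, n):
    adj = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    return [sorted(a) for a in adj]


def _pick(r, m):
    j = int(r * m)
    return m - 1 if j == m else j


def _db_winner_replay(nbrs, payoffs):
    """Replays the engine's death-birth neighbour selection (one draw)."""
    if not nbrs:
        return None
    total = sum(p for p in (payoffs[v] for v in nbrs) if p > 0.0)
    r = np.random.random()
    if total > 0.0:
        rr = r * total
        acc = 0.0
        for v in nbrs:
            if payoffs[v] > 0.0:
                acc += payoffs[v]
                if rr < acc:
                    return v
        return nbrs[-1]
    return nbrs[_pick(r, len(nbrs))]


def _global_weights(behav, slot, payoffs, t):
    """Clipped per-strategy payoff sums, engine strategy order (behav*t+slot)."""
    ns = 2 * t
    w = [0.0] * ns
    cnt = [0] * ns
    for u in range(len(behav)):
        idx = behav[u] * t + slot[u]
        w[idx] += payoffs[u]
        cnt[idx] += 1
    w = [x if (cnt[s] and x > 0.0) else 0.0 for s, x in enumerate(w)]
    if sum(w) <= 0.0:
        w = [1.0 if cnt[s] else 0.0 for s in range(ns)]
    return w


def _global_pick_replay(w, t):
    rr = np.random.random() * sum(w)
    acc = 0.0
    last = 0
    for s in range(2 * t):
        if w[s] > 0.0:
            last = s
            acc += w[s]
            if rr < acc:
                return s
    return last


def ref_run(edges, behav, slot, t, b, c, rule, update, pool, max_gens, seed,
            trace=False):
    """Pure-Python replay of the compiled engine (same seed, same draws).

    ``behav``/``slot`` are lists with 0-based slots. Returns
    ``(end_gen, fixated, behav, slot)``; with ``trace=True`` also the list of
    (behav, slot) snapshots at each census.
    """
    np.random.seed(seed)
    n = len(behav)
    behav = list(behav)
    slot = list(slot)
    nbrs = _neighbors(edges, n)
    snapshots = []
    g = 0
    while True:
        if trace:
            snapshots.append((tuple(behav), tuple(slot)))
        ncoop = sum(behav)
        if ncoop == 0 or ncoop == n:
            out = (g, 1, behav, slot)
            return out + (snapshots,) if trace else out
        if g == max_gens:
            out = (g, 0, behav, slot)
            return out + (snapshots,) if trace else out
        payoffs = ref_payoffs(edges, behav, slot, b, c)
        if rule == 0:
            if pool == 1:
                w = _global_weights(behav, slot, payoffs, t)
            if update == 0:
                u = _pick(np.random.random(), n)
                if pool == 1:
                    s = _global_pick_replay(w, t)
                    behav[u], slot[u] = s // t, s % t
                else:
                    v = _db_winner_replay(nbrs[u], payoffs)
                    if v is not None:
                        behav[u], slot[u] = behav[v], slot[v]
            else:
                newb, news = list(behav), list(slot)
                for u in range(n):
                    if pool == 1:
                        s = _global_pick_replay(w, t)
                        newb[u], news[u] = s // t, s % t
                    else:
                        v = _db_winner_replay(nbrs[u], payoffs)
                        if v is not None:
                            newb[u], news[u] = behav[v], slot[v]
                behav, slot = newb, news
        else:
            if update == 0:
                u = _pick(np.random.random(), n)
                if nbrs[u]:
                    v = nbrs[u][_pick(np.random.random(), len(nbrs[u]))]
                    if payoffs[v] > payoffs[u]:
                        behav[u], slot[u] = behav[v], slot[v]
            else:
                newb, news = list(behav), list(slot)
                for u in range(n):
                    if nbrs[u]:
                        v = nbrs[u][_pick(np.random.random(), len(nbrs[u]))]
                        if payoffs[v] > payoffs[u]:
                            newb[u], news[u] = behav[v], slot[v]
                behav, slot = newb, news
        g += 1


def ref_run_slotfree(edges, behav, rule, update, b, c, max_gens, seed):
    """Slot-free spatial PD control: no slot state anywhere in the dynamics.

    Uses the same draw conventions as the engine; with ``t = 1`` the engine
    must agree with this control generation by generation under a shared
    seed. Only the neighbour-pool regimes are meaningful here.
    """
    np.random.seed(seed)
    n = len(behav)
    behav = list(behav)
    nbrs = _neighbors(edges, n)
    snapshots = []
    g = 0
    while True:
        snapshots.append(tuple(behav))
        ncoop = sum(behav)
        if ncoop == 0 or ncoop == n or g == max_gens:
            return g, behav, snapshots
        payoffs = ref_payoffs_slotfree(edges, behav, b, c)
        if rule == 0:
            if update == 0:
                u = _pick(np.random.random(), n)
                v = _db_winner_replay(nbrs[u], payoffs)
                if v is not None:
                    behav[u] = behav[v]
            else:
                newb = list(behav)
                for u in range(n):
                    v = _db_winner_replay(nbrs[u], payoffs)
                    if v is not None:
                        newb[u] = behav[v]
                behav = newb
        else:
            if update == 0:
                u = _pick(np.random.random(), n)
                if nbrs[u]:
                    v = nbrs[u][_pick(np.random.random(), len(nbrs[u]))]
                    if payoffs[v] > payoffs[u]:
                        behav[u] = behav[v]
            else:
                newb = list(behav)
                for u in range(n):
                    if nbrs[u]:
                        v = nbrs[u][_pick(np.random.random(), len(nbrs[u]))]
                        if payoffs[v] > payoffs[u]:
                            newb[u] = behav[v]
                behav = newb
        g += 1


# -- exact one-step successor distributions --------------------------------

def _db_marginal(nbrs_u, payoffs):
    """P(site winner = v) for one death-birth site competition."""
    if not nbrs_u:
        return None
    w = [max(payoffs[v], 0.0) for v in nbrs_u]
    total = sum(w)
    if total > 0.0:
        return {v: wi / total for v, wi in zip(nbrs_u, w) if wi > 0.0}
    return {v: 1.0 / len(nbrs_u) for v in nbrs_u}


def enumerate_one_step(edges, behav, slot, t, b, c, rule, update, pool=0):
    """Exact distribution over successor states after one generation step.

    Returns a dict mapping ``(behav_tuple, slot_tuple)`` to probability.
    Synchronous regimes enumerate the product of independent per-node
    replacement marginals.
    """
    n = len(behav)
    behav = tuple(behav)
    slot = tuple(slot)
    nbrs = _neighbors(edges, n)
    payoffs = ref_payoffs(edges, behav, slot, b, c)
    dist = defaultdict(float)

    def node_marginal(u):
        """Distribution of node u's next (behavior, slot) in a sync batch."""
        if rule == 0 and pool == 1:
            w = _global_weights(behav, slot, payoffs, t)
            total = sum(w)
            return {(s // t, s % t): w[s] / total for s in range(2 * t) if w[s] > 0.0}
        if rule == 0:
            marg = _db_marginal(nbrs[u], payoffs)
            if marg is None:
                return {(behav[u], slot[u]): 1.0}
            out = defaultdict(float)
            for v, p in marg.items():
                out[(behav[v], slot[v])] += p
            return dict(out)
        # pairwise
        if not nbrs[u]:
            return {(behav[u], slot[u]): 1.0}
        out = defaultdict(float)
        p_each = 1.0 / len(nbrs[u])
        for v in nbrs[u]:
            if payoffs[v] > payoffs[u]:
                out[(behav[v], slot[v])] += p_each
            else:
                out[(behav[u], slot[u])] += p_each
        return dict(out)

    if update == 0:  # async: one uniformly chosen focal/dying node
        for u in range(n):
            for (nb, ns), p in node_marginal(u).items():
                new_b = behav[:u] + (nb,) + behav[u + 1:]
                new_s = slot[:u] + (ns,) + slot[u + 1:]
                dist[(new_b, new_s)] += p / n
    else:  # sync: independent product over nodes
        marginals = [list(node_marginal(u).items()) for u in range(n)]
        for combo in itertools.product(*marginals):
            p = 1.0
            for (_, pu) in combo:
                p *= pu
            new_b = tuple(x[0][0] for x in combo)
            new_s = tuple(x[0][1] for x in combo)
            dist[(new_b, new_s)] += p
    return dict(dist)
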