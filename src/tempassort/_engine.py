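"""Compiled full-run simulation kernel.

The generation loop (payoffs -> regime step -> fixation census) runs inside
one numba ``njit`` function so that a 10000-generation run costs
milliseconds rather than seconds; parameter sweeps execute thousands of runs.

All randomness is drawn through ``np.random.random()`` on numba's MT19937
stream (seeded once per run), with index picks computed as
``int(r * m)`` clamped to ``m - 1``. The draw order is fixed — focal choice
first, then the neighbour / strategy choice, with the second draw consumed
only when a choice exists — so a run is bit-reproducible from its seed and
can be replayed draw-for-draw by an interpreted reference implementation.

Encodings: behaviors are int8 (0 = defect, 1 = cooperate); slots are
0-based int64 here (the public API is 1-based); rule 0 = fitness
proportional, 1 = pairwise; update 0 = async, 1 = sync; pool 0 =
neighbourhood death-birth, 1 = global strategy table.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_population"]


@njit(cache=True)
def _compute_payoffs(indptr, indices, behav, slot, b, c, payoffs):
    n = behav.shape[0]
    for u in range(n):
        su = slot[u]
        bu = behav[u]
        acc = 0.0
        for j in range(indptr[u], indptr[u + 1]):
            v = indices[j]
            if slot[v] == su:
                acc += b * behav[v] - c * bu
        payoffs[u] = acc


@njit(cache=True)
def _db_winner(indptr, indices, payoffs, u):
    """Death-birth winner among u's neighbours; -1 if u is isolated.

    Consumes one uniform draw when a neighbourhood exists.
    """
    lo = indptr[u]
    hi = indptr[u + 1]
    deg = hi - lo
    if deg == 0:
        return -1
    total = 0.0
    for j in range(lo, hi):
        p = payoffs[indices[j]]
        if p > 0.0:
            total += p
    r = np.random.random()
    if total > 0.0:
        rr = r * total
        acc = 0.0
        for j in range(lo, hi):
            p = payoffs[indices[j]]
            if p > 0.0:
                acc += p
                if rr < acc:
                    return indices[j]
        return indices[hi - 1]
    jj = int(r * deg)
    if jj == deg:
        jj = deg - 1
    return indices[lo + jj]


@njit(cache=True)
def _global_table(behav, slot, payoffs, t, w, cnt):
    """Clipped payoff sum per extant strategy (index = behav * t + slot)."""
    ns = 2 * t
    for s in range(ns):
        w[s] = 0.0
        cnt[s] = 0
    n = behav.shape[0]
    for u in range(n):
        idx = behav[u] * t + slot[u]
        w[idx] += payoffs[u]
        cnt[idx] += 1
    total = 0.0
    for s in range(ns):
        if cnt[s] == 0 or w[s] < 0.0:
            w[s] = 0.0
        total += w[s]
    if total <= 0.0:  # degenerate: uniform over extant strategies
        total = 0.0
        for s in range(ns):
            w[s] = 1.0 if cnt[s] > 0 else 0.0
            total += w[s]
    return total


@njit(cache=True)
def _global_pick(w, total, t):
    """One strategy draw from the global table (one uniform consumed)."""
    rr = np.random.random() * total
    acc = 0.0
    last = 0
    for s in range(2 * t):
        if w[s] > 0.0:
            last = s
            acc += w[s]
            if rr < acc:
                return s
    return last


@njit(cache=True)
def _record(behav, slot, t, g, occ, occ_gens, n_rec):
    for s in range(t):
        occ[n_rec, s, 0] = 0
        occ[n_rec, s, 1] = 0
    for u in range(behav.shape[0]):
        if behav[u] == 1:
            occ[n_rec, slot[u], 0] += 1
        else:
            occ[n_rec, slot[u], 1] += 1
    occ_gens[n_rec] = g
    return n_rec + 1


@njit(cache=True)
def run_population(indptr, indices, behav, slot, t, b, c, rule, update, pool,
                   max_gens, seed, stride, occ, occ_gens):
    """Run up to ``max_gens`` generations in place; stop early at fixation.

    Returns ``(end_gen, fixated, n_rec)`` where ``end_gen`` is the census
    generation at which the loop stopped (the first monomorphic generation,
    or ``max_gens``), ``fixated`` is 1 if the terminal census is monomorphic
    in behavior, and ``n_rec`` is the number of occupancy records written to
    ``occ`` / ``occ_gens`` (``stride == 0`` disables recording; the terminal
    generation is always recorded when recording is on).
    """
    np.random.seed(seed)
    n = behav.shape[0]
    payoffs = np.zeros(n, dtype=np.float64)
    w = np.zeros(2 * t, dtype=np.float64)
    cnt = np.zeros(2 * t, dtype=np.int64)
    newb = np.empty(n, dtype=behav.dtype)
    news = np.empty(n, dtype=slot.dtype)
    n_rec = 0
    g = 0
    while True:
        ncoop = 0
        for u in range(n):
            ncoop += behav[u]
        done = ncoop == 0 or ncoop == n or g == max_gens
        if stride > 0 and (g % stride == 0 or done):
            n_rec = _record(behav, slot, t, g, occ, occ_gens, n_rec)
        if done:
            return g, 1 if (ncoop == 0 or ncoop == n) else 0, n_rec

        _compute_payoffs(indptr, indices, behav, slot, b, c, payoffs)

        if rule == 0:  # fitness-proportional selection
            if pool == 1:
                total = _global_table(behav, slot, payoffs, t, w, cnt)
            if update == 0:  # async: one death-birth event
                u = int(np.random.random() * n)
                if u == n:
                    u = n - 1
                if pool == 1:
                    s = _global_pick(w, total, t)
                    behav[u] = s // t
                    slot[u] = s % t
                else:
                    v = _db_winner(indptr, indices, payoffs, u)
                    if v >= 0:
                        behav[u] = behav[v]
                        slot[u] = slot[v]
            else:  # sync: replace the whole population in one batch
                for u in range(n):
                    if pool == 1:
                        s = _global_pick(w, total, t)
                        newb[u] = s // t
                        news[u] = s % t
                    else:
                        v = _db_winner(indptr, indices, payoffs, u)
                        if v >= 0:
                            newb[u] = behav[v]
                            news[u] = slot[v]
                        else:
                            newb[u] = behav[u]
                            news[u] = slot[u]
                behav[:] = newb
                slot[:] = news
        else:  # pairwise comparison: imitate strictly better sampled neighbour
            if update == 0:
                u = int(np.random.random() * n)
                if u == n:
                    u = n - 1
                deg = indptr[u + 1] - indptr[u]
                if deg > 0:
                    j = int(np.random.random() * deg)
                    if j == deg:
                        j = deg - 1
                    v = indices[indptr[u] + j]
                    if payoffs[v] > payoffs[u]:
                        behav[u] = behav[v]
                        slot[u] = slot[v]
            else:
                for u in range(n):
                    newb[u] = behav[u]
                    news[u] = slot[u]
                    deg = indptr[u + 1] - indptr[u]
                    if deg > 0:
                        j = int(np.random.random() * deg)
                        if j == deg:
                            j = deg - 1
                        v = indices[indptr[u] + j]
                        if payoffs[v] > payoffs[u]:
                            newb[u] = behav[v]
                            news[u] = slot[v]
                behav[:] = newb
                slot[:] = news
        g += 1
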