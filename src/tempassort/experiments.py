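"""Parameter sweeps with replication and the aggregate fixation statistics.

The study design crosses population size ``N`` in {100, 225, 400}, slot
count ``t`` in 1..10, and benefit ``b`` in 1..10 (cost fixed at 1), with the
small-world model additionally crossing mean degree ``k`` in {2, 3, 4} and
rewiring probability ``Pr`` in {0.05, 0.15}; every cell is replicated 7
times at G = 10000 generations. Sweep specs encode those grids; named
presets carry the full-scale defaults while replicate counts and sub-grids
remain configurable for scaled-down reproduction.

Aggregations (fixation rates, non-convergence rate, mean fixation
generation, terminal-share box statistics) operate on the serialized long
table so published result tables are re-derivable from archived CSV runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import DynamicsSpec
from .errors import ConfigurationError
from .game import Behavior, PayoffParams
from .networks import GraphKind
from .simulate import RunConfig, run

__all__ = [
    "SweepSpec",
    "SweepResult",
    "preset",
    "PRESET_NAMES",
    "run_seed",
    "run_sweep",
    "fixation_rate",
    "nonconvergence_rate",
    "mean_fixation_generation",
    "terminal_share_distribution",
]

TABLE_COLUMNS = [
    "graph_kind", "n", "t", "b", "k", "pr",
    "transition_rule", "update", "selection_pool",
    "replicate", "seed", "generations",
    "fixated", "fixed_behavior", "fixation_generation",
    "final_coop_proportion", "occupied_slots_final",
]


@dataclass(frozen=True)
class SweepSpec:
    """Grid of run configurations plus replication and seeding policy."""

    graph_kind: GraphKind = GraphKind.LATTICE
    dynamics: DynamicsSpec = field(default_factory=DynamicsSpec)
    n_values: tuple[int, ...] = (100, 225, 400)
    t_values: tuple[int, ...] = tuple(range(1, 11))
    b_values: tuple[float, ...] = tuple(float(b) for b in range(1, 11))
    k_values: tuple[int, ...] = (4,)
    pr_values: tuple[float, ...] = (0.0,)
    c: float = 1.0
    generations: int = 10_000
    replicates: int = 7
    base_seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        for name in ("n_values", "t_values", "b_values", "k_values", "pr_values"):
            if not getattr(self, name):
                raise ConfigurationError(f"{name} must be non-empty")

    def cells(self):
        """Deterministically ordered (cell_index, n, t, b, k, pr) grid."""
        grid = itertools.product(self.n_values, self.t_values, self.b_values,
                                 self.k_values, self.pr_values)
        for idx, (n, t, b, k, pr) in enumerate(grid):
            yield idx, n, t, b, k, pr

    @property
    def n_cells(self) -> int:
        return (len(self.n_values) * len(self.t_values) * len(self.b_values)
                * len(self.k_values) * len(self.pr_values))

    def restrict(self, **grids) -> "SweepSpec":
        """Sub-grid copy, e.g. ``spec.restrict(t_values=(1,), replicates=2)``."""
        return replace(self, **grids)


PRESET_NAMES = (
    "baseline-lattice",
    "baseline-smallworld",
    "sensitivity-lattice",
    "sensitivity-smallworld",
)


def preset(name: str, dynamics: DynamicsSpec | None = None,
           replicates: int = 7, base_seed: int = 0) -> SweepSpec:
    """Named full-scale sweep grids.

    ``baseline-*`` presets default to fitness-proportional / asynchronous
    dynamics; ``sensitivity-*`` presets take the regime as an argument and
    fix Pr = 0.05 on the small-world graph (the baseline established the
    rewiring probability as inconsequential, so sensitivity grids keep only
    one value).
    """
    dyn = dynamics or DynamicsSpec()
    common = dict(dynamics=dyn, replicates=replicates, base_seed=base_seed)
    if name == "baseline-lattice":
        return SweepSpec(graph_kind=GraphKind.LATTICE, **common)
    if name == "baseline-smallworld":
        return SweepSpec(graph_kind=GraphKind.SMALL_WORLD,
                         k_values=(2, 3, 4), pr_values=(0.05, 0.15), **common)
    if name == "sensitivity-lattice":
        return SweepSpec(graph_kind=GraphKind.LATTICE, **common)
    if name == "sensitivity-smallworld":
        return SweepSpec(graph_kind=GraphKind.SMALL_WORLD,
                         k_values=(2, 3, 4), pr_values=(0.05,), **common)
    raise ConfigurationError(
        f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")


def run_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Reproducible per-run seed, independent of execution order or worker."""
    ss = np.random.SeedSequence([base_seed, cell_index, replicate])
    return int(ss.generate_state(1)[0] >> 1)


@dataclass
class SweepResult:
    """Long table of per-run summaries, one row per (cell, replicate)."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, columns=TABLE_COLUMNS)

    @classmethod
    def from_csv(cls, path) -> "SweepResult":
        df = pd.read_csv(path, dtype={"fixed_behavior": "string"})
        return cls(df[TABLE_COLUMNS])


def run_sweep(spec: SweepSpec, progress: bool = False) -> SweepResult:
    """Execute every cell x replicate of the grid; deterministic given base_seed."""
    rows = []
    cells = list(spec.cells())
    iterator = cells
    if progress:
        from tqdm import tqdm
        iterator = tqdm(cells, unit="cell")
    lattice_cache: dict[int, object] = {}  # deterministic per n; reuse across runs
    for idx, n, t, b, k, pr in iterator:
        if spec.graph_kind is GraphKind.LATTICE and n not in lattice_cache:
            from .networks import build_lattice
            lattice_cache[n] = build_lattice(n)
        for rep in range(spec.replicates):
            seed = run_seed(spec.base_seed, idx, rep)
            config = RunConfig(
                n=n, t=t, params=PayoffParams(b=b, c=spec.c),
                graph_kind=spec.graph_kind, k=k, pr=pr,
                dynamics=spec.dynamics, generations=spec.generations,
                seed=seed,
            )
            try:
                res = run(config, graph=lattice_cache.get(n))
            except Exception as exc:  # identify the offending cell, then abort
                raise RuntimeError(
                    f"run failed in cell (n={n}, t={t}, b={b}, k={k}, pr={pr}), "
                    f"replicate {rep}: {exc}") from exc
            rows.append({
                "graph_kind": spec.graph_kind.value, "n": n, "t": t, "b": b,
                "k": k, "pr": pr,
                "transition_rule": spec.dynamics.transition_rule.value,
                "update": spec.dynamics.update.value,
                "selection_pool": spec.dynamics.selection_pool.value,
                "replicate": rep, "seed": seed, "generations": spec.generations,
                "fixated": res.fixated,
                "fixed_behavior": (res.fixed_behavior.letter
                                   if res.fixed_behavior is not None else pd.NA),
                "fixation_generation": res.fixation_generation if res.fixated else np.nan,
                "final_coop_proportion": res.final_coop_proportion,
                "occupied_slots_final": res.occupied_slots_final,
            })
    return SweepResult(pd.DataFrame(rows, columns=TABLE_COLUMNS))


# -- aggregations ----------------------------------------------------------


def _select(result: SweepResult | pd.DataFrame, where) -> pd.DataFrame:
    df = result.table if isinstance(result, SweepResult) else result
    if where is None:
        out = df
    elif callable(where):
        out = df[where(df)]
    elif isinstance(where, dict):
        mask = pd.Series(True, index=df.index)
        for col, val in where.items():
            if isinstance(val, (list, tuple, set, range, np.ndarray)):
                mask &= df[col].isin(list(val))
            else:
                mask &= df[col] == val
        out = df[mask]
    else:
        raise ConfigurationError(f"unsupported filter {where!r}")
    if out.empty:
        raise ConfigurationError("selection matched no runs")
    return out


def fixation_rate(result, where=None, behavior: Behavior = Behavior.COOPERATE) -> float:
    """Percentage of selected runs ending in fixation of ``behavior``."""
    df = _select(result, where)
    hit = (df["fixated"] == True) & (df["fixed_behavior"] == behavior.letter)  # noqa: E712
    return 100.0 * hit.mean()


def nonconvergence_rate(result, where=None) -> float:
    """Percentage of selected runs with no behavioral fixation by G."""
    df = _select(result, where)
    return 100.0 * (df["fixated"] == False).mean()  # noqa: E712


def mean_fixation_generation(result, where=None,
                             behavior: Behavior = Behavior.COOPERATE) -> float:
    """Mean fixation generation over selected runs fixed for ``behavior``."""
    df = _select(result, where)
    sub = df[(df["fixated"] == True) & (df["fixed_behavior"] == behavior.letter)]  # noqa: E712
    if sub.empty:
        raise ConfigurationError(
            f"no {behavior.letter}-fixated runs in selection")
    return float(sub["fixation_generation"].mean())


def terminal_share_distribution(result, by: str = "t") -> pd.DataFrame:
    """Tukey box-plot statistics of the terminal cooperator share per group.

    Whiskers extend to the most extreme values within 1.5 x IQR of the
    quartiles; values beyond are counted as outliers.
    """
    df = _select(result, None)
    rows = []
    for key, grp in df.groupby(by):
        x = grp["final_coop_proportion"].to_numpy()
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        in_lo = x[x >= q1 - 1.5 * iqr]
        in_hi = x[x <= q3 + 1.5 * iqr]
        rows.append({
            by: key, "n_runs": len(x), "median": med, "q1": q1, "q3": q3,
            "whisker_low": in_lo.min() if in_lo.size else q1,
            "whisker_high": in_hi.max() if in_hi.size else q3,
            "n_outliers": int(((x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)).sum()),
        })
    return pd.DataFrame(rows).set_index(by)
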