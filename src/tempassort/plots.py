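"""Optional matplotlib renderings of sweep aggregates.

Two views of a sweep table: the b x t cooperator-fixation heatmap (one panel
per population size) and per-t box plots of the terminal cooperator share.
"""

from __future__ import annotations

import numpy as np

from .experiments import SweepResult

__all__ = ["plot_fixation_heatmap", "plot_terminal_share_box"]


def plot_fixation_heatmap(result: SweepResult, behavior_letter: str = "C"):
    """Fraction of runs fixing `behavior` per (b, t) cell, one panel per N."""
    import matplotlib.pyplot as plt

    df = result.table.copy()
    df["hit"] = (df["fixated"] == True) & (df["fixed_behavior"] == behavior_letter)  # noqa: E712
    ns = sorted(df["n"].unique())
    ts = sorted(df["t"].unique())
    bs = sorted(df["b"].unique())
    fig, axes = plt.subplots(1, len(ns), figsize=(4 * len(ns), 3.5),
                             squeeze=False, constrained_layout=True)
    for ax, n in zip(axes[0], ns):
        sub = df[df["n"] == n]
        grid = np.full((len(ts), len(bs)), np.nan)
        rate = sub.groupby(["t", "b"])["hit"].mean()
        for (t, b), v in rate.items():
            grid[ts.index(t), bs.index(b)] = v
        im = ax.imshow(grid, origin="lower", vmin=0, vmax=1, aspect="auto",
                       extent=(min(bs) - 0.5, max(bs) + 0.5,
                               min(ts) - 0.5, max(ts) + 0.5))
        ax.set_xlabel("benefit b")
        ax.set_ylabel("time slots t")
        ax.set_title(f"N = {n}")
    fig.colorbar(im, ax=axes[0], label=f"fraction of runs fixing {behavior_letter}")
    return fig


def plot_terminal_share_box(result: SweepResult, by: str = "t"):
    """Tukey box plots of the terminal cooperator share, grouped by `by`."""
    import matplotlib.pyplot as plt

    df = result.table
    keys = sorted(df[by].unique())
    data = [df.loc[df[by] == key, "final_coop_proportion"].to_numpy() for key in keys]
    fig, ax = plt.subplots(figsize=(1 + 0.8 * len(keys), 3.5), constrained_layout=True)
    ax.boxplot(data, tick_labels=[str(k) for k in keys], whis=1.5)
    ax.set_xlabel(by)
    ax.set_ylabel("cooperator share at final generation")
    ax.set_ylim(-0.02, 1.02)
    return fig
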