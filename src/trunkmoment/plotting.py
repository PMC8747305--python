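"""Summary figures for study results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

SET_ORDER = ("quasi_static", "worst_selected", "full")
SET_COLORS = {"quasi_static": "#c44e52", "worst_selected": "#dd8452",
              "full": "#4c72b0"}


def plot_task_group_bars(result, path=None):
    """Grouped bars of task-group RMSE per calibration set, one panel per
    model (mirrors the final three-set comparison)."""
    table = result.task_group
    groups = sorted(table["task_group"].unique())
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
    for ax, model in zip(axes, ("emgmod", "regmod")):
        sub = table[table["model"] == model]
        x = np.arange(len(groups))
        width = 0.25
        for k, set_label in enumerate(SET_ORDER):
            means = [sub[(sub["task_group"] == g)
                         & (sub["set_label"] == set_label)]["rmse"].mean()
                     for g in groups]
            sds = [sub[(sub["task_group"] == g)
                       & (sub["set_label"] == set_label)]["rmse"].std()
                   for g in groups]
            ax.bar(x + (k - 1) * width, means, width, yerr=sds, capsize=2,
                   label=set_label, color=SET_COLORS[set_label])
        ax.set_xticks(x)
        ax.set_xticklabels(groups, rotation=30, ha="right")
        ax.set_title(model)
        ax.set_ylabel("human-moment RMSE (N·m)")
    axes[0].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_rmse_vs_n(result, path=None):
    """RMSE of every evaluated subset against its size, with the Full-set
    reference level as a dashed line."""
    sweep = result.sweep
    if sweep is None:
        raise ValueError("study was run without the subset sweep")
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, model in zip(axes, ("emgmod", "regmod")):
        col = f"{model}_rmse"
        jitter = (np.random.default_rng(0)
                  .uniform(-0.12, 0.12, size=len(sweep)))
        ax.plot(sweep["n"] + jitter, sweep[col], ".", alpha=0.4,
                label="subsets")
        best = sweep.groupby("n")[col].min()
        ax.plot(best.index, best.values, "o-", color="k", label="best subset")
        full_level = result.mean_rmse("full", model)
        ax.axhline(full_level, ls="--", color="#4c72b0", label="Full set")
        ax.set_xlabel("calibration trials in set (n)")
        ax.set_title(model)
        ax.set_ylabel("human-moment RMSE (N·m)")
    axes[0].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
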