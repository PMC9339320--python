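"""Basic trajectory and ECDF plots for simulation output."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_trajectories", "plot_pv_ecdf"]


def plot_trajectories(metrics: pd.DataFrame, path: str) -> None:
    """Per-method mean trajectories of the four criteria over generations."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    panels = ["mean_gebv", "lower_potential", "upper_potential", "best_gebv"]
    for ax, column in zip(axes.ravel(), panels):
        for method, group in metrics.groupby("method"):
            trajectory = group.groupby("generation")[column].mean()
            ax.plot(trajectory.index, trajectory.values, marker="o", label=method)
        ax.set_title(column.replace("_", " "))
        ax.set_xlabel("generation")
    axes[0, 0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pv_ecdf(summaries: dict, path: str) -> None:
    """Empirical CDFs of the replicate present values, one curve per method."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for method, summary in summaries.items():
        ecdf = summary["pv_ecdf"]
        ax.step(ecdf["value"], ecdf["prob"], where="post", label=method)
    ax.set_xlabel("present value of GEBV")
    ax.set_ylabel("empirical CDF")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
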