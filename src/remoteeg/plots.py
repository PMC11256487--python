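"""Headless figure panels for the three analyses (matplotlib Agg)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .erp_stats import ClusterTestResult, EpochSet, average_erp

__all__ = ["plot_band_powers", "plot_erp", "plot_confusion"]


def plot_band_powers(table: pd.DataFrame, path: str | Path, band: str = "alpha") -> Path:
    """Violin plot of one band's relative power per condition (per channel)."""
    channels = list(dict.fromkeys(table["channel"]))
    fig, axes = plt.subplots(1, len(channels), figsize=(3 * len(channels), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, ch in zip(axes, channels):
        sub = table[table["channel"] == ch]
        conditions = sorted(set(sub["condition"]))
        data = [sub.loc[sub["condition"] == c, band] for c in conditions]
        ax.violinplot(data, showmeans=True)
        ax.set_xticks(range(1, len(conditions) + 1), conditions, rotation=20)
        ax.set_title(ch)
    axes[0].set_ylabel(f"relative {band} power")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_erp(
    epochs: EpochSet,
    results: dict[str, ClusterTestResult] | None,
    path: str | Path,
    alpha: float = 0.01,
) -> Path:
    """Per-channel condition-average ERPs with significant clusters shaded."""
    averages = average_erp(epochs)
    channels = epochs.channel_names or tuple(str(i) for i in range(epochs.n_channels))
    fig, axes = plt.subplots(1, len(channels), figsize=(3.2 * len(channels), 3.0), sharey=True)
    axes = np.atleast_1d(axes)
    colors = {"oddball": "tab:blue", "standard": "tab:green"}
    for i, (ax, ch) in enumerate(zip(axes, channels)):
        for cond, (mean, sem) in averages.items():
            ax.plot(epochs.times, mean[i], label=cond, color=colors.get(cond))
            ax.fill_between(
                epochs.times, mean[i] - sem[i], mean[i] + sem[i],
                alpha=0.2, color=colors.get(cond),
            )
        if results and ch in results:
            for cl in results[ch].significant(alpha):
                ax.axvspan(cl.start_s, cl.end_s, color="red", alpha=0.15)
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_title(ch)
        ax.set_xlabel("time (s)")
    axes[0].set_ylabel("amplitude (uV)")
    axes[-1].legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_confusion(confusion: np.ndarray, classes: tuple[str, ...], path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    im = ax.imshow(confusion, cmap="Blues")
    for (i, j), v in np.ndenumerate(confusion):
        ax.text(j, i, str(int(v)), ha="center", va="center")
    ax.set_xticks(range(len(classes)), classes)
    ax.set_yticks(range(len(classes)), classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
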