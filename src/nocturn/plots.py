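"""Figure exports: hypnogram lane plots and group time courses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import Hypnogram, State

__all__ = ["plot_hypnogram", "plot_group_timecourse"]

_LANES = {State.WAKE: 2, State.NREM: 1, State.REM: 0}


def plot_hypnogram(hypnogram: Hypnogram, path=None, title: str | None = None):
    """24-h hypnogram in W/N/R lanes with an LD bar underneath."""
    fig, ax = plt.subplots(figsize=(10, 2.2))
    zt_h = hypnogram.zt_s() / 3600.0
    lanes = np.vectorize(lambda s: _LANES[State(int(s))])(hypnogram.states)
    ax.step(zt_h, lanes, where="post", lw=0.4, color="black")
    ax.set_yticks([0, 1, 2], ["R", "N", "W"])
    ax.set_xlabel("Zeitgeber time (h)")
    ax.set_xlim(zt_h[0], zt_h[-1] + hypnogram.epoch_length_s / 3600.0)
    ax.set_ylim(-0.9, 2.3)
    # LD bar: white = light, black = dark.
    light = hypnogram.light_mask()
    ax.fill_between(zt_h, -0.8, -0.4, where=~light, step="post",
                    color="black")
    ax.fill_between(zt_h, -0.8, -0.4, where=light, step="post",
                    color="white", edgecolor="black", lw=0.3)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_group_timecourse(tables: dict[str, list[pd.Series]], ylabel: str,
                          path=None):
    """Group mean ± SEM time courses; ``tables`` maps group name to a
    list of per-animal series indexed by ZT bin (hours)."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    for group, series_list in tables.items():
        mat = pd.concat(series_list, axis=1)
        mean = mat.mean(axis=1)
        sem = mat.std(axis=1, ddof=1) / np.sqrt(mat.shape[1])
        ax.errorbar(mean.index, mean, yerr=sem, label=group,
                    marker="o", ms=3, capsize=2)
    ax.set_xlabel("Zeitgeber time (h)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
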