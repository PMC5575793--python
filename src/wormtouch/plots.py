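"""Minimal figure helpers: ensemble traces, dose-response grids, screen boxes."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metrics import GridSummary, ensemble_mean_sem

__all__ = ["plot_mean_sem", "plot_grid_bubbles", "plot_screen_boxes"]


def plot_mean_sem(traces, protocol=None, ax=None):
    """Frame-wise mean +/- SEM dR/R0 over trials, with stimulus bars."""
    df = ensemble_mean_sem(traces)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.fill_between(
        df["time_s"],
        df["mean_dRR"] - df["sem_dRR"],
        df["mean_dRR"] + df["sem_dRR"],
        alpha=0.3,
        lw=0,
    )
    ax.plot(df["time_s"], df["mean_dRR"], lw=1.5)
    if protocol is not None:
        for onset, dur in zip(protocol.onsets, protocol.durations):
            ax.axvspan(onset, onset + dur, color="0.85", zorder=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(r"$\Delta R/R_0$")
    return ax


def plot_grid_bubbles(summary: GridSummary, ax=None, max_peak: float = 3.0):
    """Bubble chart of a pressure x duration grid: circle area = mean peak,
    square area = response fraction."""
    t = summary.table
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    peak_size = 600 * np.clip(t["mean_peak"] / max_peak, 0, 1)
    frac_size = 600 * t["response_fraction"]
    ax.scatter(t["pressure"], t["duration"], s=peak_size, alpha=0.6, label="mean peak")
    ax.scatter(
        t["pressure"], t["duration"], s=frac_size, marker="s",
        facecolors="none", edgecolors="k", label="response fraction",
    )
    ax.set_xlabel("pressure (psi)")
    ax.set_ylabel("duration (s)")
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_screen_boxes(report, metric: str = "max_dRR", ax=None):
    """Box plots of same-day-normalized metric values per group, control first."""
    sub = report.normalized[report.normalized["metric"] == metric].dropna(
        subset=["value"]
    )
    groups = ["control"] + sorted(c for c in sub["compound"].unique() if c != "control")
    data = [sub.loc[sub["compound"] == g, "value"] for g in groups]
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + len(groups), 3.5))
    ax.boxplot(data, tick_labels=groups)
    ax.axhline(1.0, color="0.6", lw=0.8, ls="--")
    ax.set_ylabel(f"{metric} (normalized to same-day control)")
    ax.tick_params(axis="x", rotation=45)
    return ax
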