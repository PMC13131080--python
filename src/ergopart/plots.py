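"""Figure-style plots: recovery-fit panels and MPV trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .dataio import RepetitionTable
from .kinetics import BiExpFit, SmoothedSeries
from .velocity import normalize_mpv

__all__ = ["plot_recovery_fit", "plot_mpv"]


def plot_recovery_fit(series: SmoothedSeries, fit: BiExpFit, path=None):
    """Recovery window: smoothed series, bi-exponential fit, fast component
    (dashed) and the fitted baseline line."""
    t0 = fit.recovery_start_s
    t, v = series.window(t0, series.grid_time_s[-1])
    ts = t - t0
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(ts, v * 60.0, color="0.6", lw=0.8, label="smoothed $\\dot{V}O_2$")
    ax.plot(ts, fit.predict(ts) * 60.0, color="crimson", lw=1.6, label="bi-exponential fit")
    ax.plot(
        ts,
        (fit.a * np.exp(-ts / fit.tau_a) + fit.c) * 60.0,
        color="royalblue", ls="--", lw=1.2, label="fast component + c",
    )
    ax.axhline(fit.c * 60.0, color="black", lw=1.0, label="baseline c")
    ax.set_xlabel("time since recovery start (s)")
    ax.set_ylabel("$\\dot{V}O_2$ (L/min)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_mpv(tables: dict[str, RepetitionTable], path=None):
    """Absolute and percent-of-fastest MPV per repetition, one line per
    participant session (keys label the lines, e.g. 'P01 CS')."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for label, table in tables.items():
        frame = normalize_mpv(table)
        frame = frame.sort_values(["set_index", "rep_index"])
        x = np.arange(len(frame))
        axes[0].plot(x, frame["mpv_m_s"], marker="o", ms=3, lw=0.8, label=label)
        axes[1].plot(x, frame["pct_of_fastest"], marker="o", ms=3, lw=0.8, label=label)
    axes[0].set_ylabel("MPV (m/s)")
    axes[1].set_ylabel("MPV (% of set's fastest rep)")
    for ax in axes:
        ax.set_xlabel("repetition (session order)")
    axes[0].legend(frameon=False, fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
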