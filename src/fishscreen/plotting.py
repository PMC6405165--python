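"""Minimal plotting helpers for traces, rankings and movement summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_traces(traces: pd.DataFrame, ax=None):
    """Normalized fluorescence per condition over hpf (mean across wells)."""
    if ax is None:
        _, ax = plt.subplots()
    df = traces
    if "channel_role" in df.columns and (df["channel_role"] == "test").any():
        df = df[df["channel_role"] == "test"]
    for condition, grp in df.groupby("condition"):
        m = grp.groupby("time_hpf")["value"].mean()
        ax.plot(m.index, m.values, label=condition)
    ax.set_xlabel("hours post fertilization")
    ax.set_ylabel("normalized fluorescence")
    ax.legend(fontsize="small")
    return ax


def plot_movement(summary: pd.DataFrame, ax=None):
    """Mean movement index per condition over time, with +/- sd band."""
    if ax is None:
        _, ax = plt.subplots()
    for condition, grp in summary.groupby("condition"):
        grp = grp.sort_values("time_hpf")
        ax.plot(grp["time_hpf"], grp["mean"], label=condition)
        ax.fill_between(grp["time_hpf"], grp["mean"] - grp["sd"],
                        grp["mean"] + grp["sd"], alpha=0.2)
    ax.set_xlabel("hours post fertilization")
    ax.set_ylabel("movement index")
    ax.legend(fontsize="small")
    return ax
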