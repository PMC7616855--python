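"""Matplotlib helpers for the standard figures of the analyses."""

from __future__ import annotations

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_mds_trajectories", "plot_level_histogram",
           "plot_training_history", "plot_erf_survey"]


def plot_mds_trajectories(coords: np.ndarray, layer_names: list[str],
                          ax=None):
    """2-d MDS embedding of layers; layers of one model joined by a line.

    ``layer_names`` are "model/layer" strings; the model prefix groups the
    trajectory.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    models = pd.Series([n.split("/")[0] for n in layer_names])
    for model in models.unique():
        idx = np.nonzero((models == model).to_numpy())[0]
        ax.plot(coords[idx, 0], coords[idx, 1], marker="o", ms=3,
                label=model)
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    ax.legend(fontsize=8)
    return ax


def plot_level_histogram(hist: pd.Series, ax=None, label=None):
    """Bar chart of the per-image deepest MIRC level distribution."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.bar(hist.index, hist.values, width=0.8, label=label)
    ax.set_xlabel("MIRC level")
    ax.set_ylabel("images")
    if label:
        ax.legend()
    return ax


def plot_training_history(history, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    frame = history.to_frame()
    ax.plot(frame["epoch"], frame["loss"], label="loss")
    ax2 = ax.twinx()
    ax2.plot(frame["epoch"], frame["accuracy"], color="C1", label="accuracy")
    ax.set_xlabel("epoch")
    ax.set_ylabel("loss")
    ax2.set_ylabel("accuracy")
    return ax


def plot_erf_survey(results: pd.DataFrame, ax=None):
    """Test accuracy against analytic ERF (one point per variant/seed)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    agg = results.groupby("erf")["test_accuracy"].agg(["mean", "std"])
    ax.errorbar(agg.index, agg["mean"], yerr=agg["std"].fillna(0),
                marker="o")
    ax.set_xlabel("ERF (px)")
    ax.set_ylabel("test accuracy")
    ax.set_xscale("log")
    return ax
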