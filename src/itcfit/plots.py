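"""Matplotlib figures for diagnostics: convergence, calibration, KL maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["convergence_plot", "coverage_plot", "kl_heatmap", "heat_curve_plot"]


def convergence_plot(report: pd.DataFrame, parameters=None):
    """Running credible-interval bounds per chain, one panel per parameter."""
    parameters = list(parameters or report.index)
    fig, axes = plt.subplots(
        len(parameters), 1, figsize=(6, 2.2 * len(parameters)), squeeze=False
    )
    for ax, name in zip(axes[:, 0], parameters):
        row = report.loc[name]
        ck = row["checkpoints"]
        for chain_bounds in row["running_bounds"]:
            b = np.array(chain_bounds)
            ax.plot(ck, b[:, 0], "k-", lw=0.6)
            ax.plot(ck, b[:, 1], "k-", lw=0.6)
        ax.errorbar(
            [ck[-1]] * 2,
            [row["mean_lower"], row["mean_upper"]],
            yerr=[row["sd_lower"], row["sd_upper"]],
            fmt="ro",
            ms=3,
        )
        ax.set_ylabel(name)
    axes[-1, 0].set_xlabel("stored samples")
    fig.tight_layout()
    return fig


def coverage_plot(curves: dict[str, pd.DataFrame]):
    """Predicted vs observed containment rate, one series per method."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 100], [0, 100], "k-", lw=1)
    for label, df in curves.items():
        ax.errorbar(
            100 * df["level"],
            100 * df["observed"],
            yerr=100 * df["bootstrap_sd"],
            fmt="o",
            ms=4,
            label=label,
        )
    ax.set_xlabel("predicted rate (%)")
    ax.set_ylabel("observed rate (%)")
    ax.legend()
    fig.tight_layout()
    return fig


def kl_heatmap(matrix: np.ndarray, title: str = ""):
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix, cmap="viridis")
    fig.colorbar(im, ax=ax, label="ln KL divergence")
    ax.set_xlabel("dataset")
    ax.set_ylabel("dataset")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def heat_curve_plot(heats_cal, model_heats_cal=None):
    """Observed (and optionally modelled) integrated heats in ucal."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    q = np.asarray(heats_cal) * 1e6
    ax.plot(np.arange(1, q.size + 1), q, "ko", ms=4, label="observed")
    if model_heats_cal is not None:
        ax.plot(
            np.arange(1, q.size + 1),
            np.asarray(model_heats_cal) * 1e6,
            "r-",
            label="model",
        )
        ax.legend()
    ax.set_xlabel("injection")
    ax.set_ylabel("heat (ucal)")
    fig.tight_layout()
    return fig
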