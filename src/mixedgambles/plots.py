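"""Figures: condition-wise accept-proportion bars and rank histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .recovery import RecoveryReport


def plot_proportion_panels(
    predicted: pd.DataFrame, observed: pd.DataFrame | None = None
):
    """Bar panels of mean accept proportion per condition.

    Left panel: model predictions on the common gambles; right panel (if
    given): proportions observed in (simulated or real) choice data.
    """
    n_panels = 2 if observed is not None else 1
    fig, axes = plt.subplots(1, n_panels, figsize=(4 * n_panels, 3.2), squeeze=False)
    panels = [("Predicted (DbS)", predicted, "mean_accept")]
    if observed is not None:
        panels.append(("Observed", observed, "proportion"))
    for ax, (title, frame, col) in zip(axes[0], panels):
        ax.bar(frame["condition"], frame[col], color="0.4")
        ax.axhline(0.5, color="k", lw=0.8, ls="--")
        ax.set_ylim(0, 1)
        ax.set_ylabel("P(accept) on common gambles")
        ax.set_xlabel("condition (max gain, max loss)")
        ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_rank_histograms(report: RecoveryReport):
    """One panel per target percentile: second-half rank distributions.

    Dark bars: observed ranks ("stochasticity and generalization"); light
    bars: the stochasticity-only null, when present.
    """
    pcts = report.percentiles
    fig, axes = plt.subplots(1, len(pcts), figsize=(2.6 * len(pcts), 2.8), sharey=True)
    axes = np.atleast_1d(axes)
    bins = np.linspace(0.5, report.n_agents + 0.5, min(report.n_agents, 20) + 1)
    for ax, pct in zip(axes, pcts):
        ax.hist(
            report.rank_distributions[pct], bins=bins, color="firebrick",
            alpha=0.7, label="observed",
        )
        if report.null_distributions is not None:
            ax.hist(
                report.null_distributions[pct], bins=bins, color="seagreen",
                alpha=0.6, label="stochasticity alone",
            )
        ax.set_title(f"{pct}th percentile")
        ax.set_xlabel("second-half rank")
    axes[0].set_ylabel("replicates")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    return fig
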