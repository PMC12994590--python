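"""Matplotlib figures for diagnostics and simulation output.

Quantitative content only — every plotted number is available from the
corresponding tables (draws, PPC bands, ensemble bands).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bayes import PosteriorDraws
from .diagnostics import PPCBands
from .simulate import SimulationEnsemble

__all__ = ["plot_trace", "plot_ppc", "plot_ensemble"]


def plot_trace(draws: PosteriorDraws, params=None, path=None):
    """Per-chain trace plots; one panel per parameter."""
    params = list(params or draws.param_names)
    fig, axes = plt.subplots(
        len(params), 1, figsize=(8, 1.8 * len(params)), sharex=True, squeeze=False
    )
    for ax, name in zip(axes[:, 0], params):
        x = draws.parameter(name)
        for c in range(x.shape[0]):
            ax.plot(x[c], lw=0.4, alpha=0.7)
        ax.set_ylabel(name, fontsize=8)
    axes[-1, 0].set_xlabel("draw")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_ppc(bands: PPCBands, ds=None, path=None):
    """PPC percentile ribbons per analyte, observations overlaid."""
    analytes = bands.bands["analyte"].unique()
    fig, axes = plt.subplots(1, len(analytes), figsize=(6 * len(analytes), 4), squeeze=False)
    for ax, analyte in zip(axes[0], analytes):
        b = bands.bands[bands.bands["analyte"] == analyte]
        ax.fill_between(b["time_h"], b["p5"], b["p95"], alpha=0.25, label="5th-95th")
        ax.fill_between(b["time_h"], b["p25"], b["p75"], alpha=0.35, label="25th-75th")
        ax.plot(b["time_h"], b["p50"], lw=1.2, label="median")
        if ds is not None:
            o = ds.analyte(analyte)
            ax.errorbar(
                o["time_h"], o["mean_ng_ml"], yerr=o["sd_ng_ml"],
                fmt="o", ms=4, mfc="none", color="k", lw=0.8, label="observed",
            )
        ax.set_title(analyte)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (ng/mL)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_ensemble(ens: SimulationEnsemble, log_scale=False, path=None):
    """Repeated-dose median profile with 95 % uncertainty ribbon."""
    analytes = ens.bands["analyte"].unique()
    fig, axes = plt.subplots(1, len(analytes), figsize=(6 * len(analytes), 4), squeeze=False)
    for ax, analyte in zip(axes[0], analytes):
        b = ens.bands[ens.bands["analyte"] == analyte]
        ax.fill_between(b["time_h"], b["lower"], b["upper"], alpha=0.3, label="95% interval")
        ax.plot(b["time_h"], b["median"], lw=1.2, label="median")
        if log_scale:
            ax.set_yscale("log")
        ax.set_title(analyte)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (ng/mL)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
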