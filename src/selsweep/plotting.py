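"""Matplotlib figures for the standard outputs (LD decay, Manhattan panels)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_ld_decay", "plot_manhattan", "plot_fst_windows"]


def plot_ld_decay(bins_by_pop: dict[str, pd.DataFrame], path=None):
    """Mean r^2 per 100 kb distance bin, one curve per population."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for pop, df in bins_by_pop.items():
        ok = df["n_pairs"] > 0
        x = (df.loc[ok, "bin_lo"] + df.loc[ok, "bin_hi"]) / 2 / 1e3
        ax.plot(x, df.loc[ok, "mean_r2"], marker="o", ms=3, label=pop)
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel(r"mean $r^2$")
    ax.legend(title="population")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_manhattan(scores: pd.DataFrame, threshold: float = 7.4, title: str = "", path=None):
    """-log10 p along the genome with the significance line."""
    fig, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    for chrom, grp in scores.groupby("chrom", sort=True):
        ok = np.isfinite(grp["neg_log10_p"])
        ax.scatter(
            grp.loc[ok, "pos"] + offset, grp.loc[ok, "neg_log10_p"], s=4, alpha=0.6
        )
        offset += int(grp["pos"].max()) if len(grp) else 0
    ax.axhline(threshold, color="red", lw=1, ls="--")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_fst_windows(windows: pd.DataFrame, top: pd.DataFrame | None = None, title: str = "", path=None):
    """Sliding-window weighted F_ST, with the top-fraction windows marked."""
    fig, ax = plt.subplots(figsize=(8, 3))
    ok = np.isfinite(windows["value"])
    mid = (windows["start"] + windows["end"]) / 2
    ax.scatter(mid[ok], windows.loc[ok, "value"], s=4, alpha=0.6, color="grey")
    if top is not None and len(top):
        mid_t = (top["start"] + top["end"]) / 2
        ax.scatter(mid_t, top["value"], s=8, color="orange")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(r"weighted $F_{ST}$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
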