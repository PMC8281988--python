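"""Matplotlib renderings: sparkler plots, correlation heat maps, overlaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["sparkler_plot", "correlation_heatmap", "overlap_plot"]

CALL_COLORS = {
    "GOF": "#d62728",
    "LOF": "#1f77b4",
    "COF": "#9467bd",
    "Neutral": "#2ca02c",
    "NI": "#7f7f7f",
}


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def sparkler_plot(frame: pd.DataFrame, path=None, ax=None):
    """Variant scatter: x = -log10 adjusted impact p, y = direction score."""
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(5, 4))
    for call, sub in frame.groupby("call"):
        ax.scatter(sub["x"], sub["y"], label=call,
                   color=CALL_COLORS.get(call, "black"), s=40, zorder=3)
    for _, row in frame.iterrows():
        ax.annotate(str(row["variant"]), (row["x"], row["y"]),
                    textcoords="offset points", xytext=(4, 4), fontsize=7)
    ax.axhline(0, color="0.8", lw=0.8, zorder=1)
    ax.set_xlabel("impact test  $-\\log_{10}$(adjusted p)")
    ax.set_ylabel("impact direction score")
    ax.legend(fontsize=8, frameon=False)
    return _finish(fig, path)


def correlation_heatmap(corr: pd.DataFrame, path=None, ax=None):
    """Sample-by-sample Spearman correlation heat map."""
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.columns)))
    ax.set_xticklabels(corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr.index)))
    ax.set_yticklabels(corr.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    return _finish(fig, path)


def overlap_plot(intersections: pd.DataFrame, path=None, ax=None):
    """Bar panel of exact pathway-intersection sizes (UpSet-style)."""
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(6, 3.5))
    sub = intersections[intersections["pathways"] != ""]
    ax.bar(np.arange(len(sub)), sub["n_genes"], color="0.3")
    ax.set_xticks(np.arange(len(sub)))
    ax.set_xticklabels(sub["pathways"], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("genes in exact intersection")
    return _finish(fig, path)
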