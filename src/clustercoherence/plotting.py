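"""Heatmap and profile figures for screen and coherence matrices."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["heatmap", "profile_plot"]


def heatmap(
    df: pd.DataFrame,
    path: str | Path,
    title: str = "",
    cmap: str = "coolwarm",
    vmin: float | None = None,
    vmax: float | None = None,
) -> None:
    """Save a labelled heatmap of a (small) matrix; NaN cells are blank."""
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * df.shape[1] + 2), max(3, 0.25 * df.shape[0] + 1.5))
    )
    data = df.to_numpy(dtype=float)
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xticks(range(df.shape[1]))
    ax.set_xticklabels(df.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(df.shape[0]))
    ax.set_yticklabels(df.index, fontsize=6)
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def profile_plot(
    values: pd.DataFrame,
    path: str | Path,
    title: str = "",
    pcc: float | None = None,
) -> None:
    """Per-gene expression profiles across timepoints (one line per gene)."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    x = np.arange(values.shape[1])
    for _, row in values.iterrows():
        ax.plot(x, row.to_numpy(), lw=0.8, alpha=0.7)
    ax.set_xticks(x)
    ax.set_xticklabels(values.columns, fontsize=7)
    ax.set_xlabel("timepoint")
    ax.set_ylabel("log2 expression")
    label = title
    if pcc is not None and np.isfinite(pcc):
        label = f"{title} (PCC = {pcc:.3f})" if title else f"PCC = {pcc:.3f}"
    if label:
        ax.set_title(label, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
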