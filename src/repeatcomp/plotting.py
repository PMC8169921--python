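"""Minimal plotting: saddle heatmap with corner-strength annotation."""

from __future__ import annotations

import numpy as np

from .hic import SaddleResult

__all__ = ["plot_saddle"]


def plot_saddle(result: SaddleResult, ax=None, cmap: str = "coolwarm"):
    """Log2 saddle heatmap, B-like quantiles top-left, strength in the center."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    with np.errstate(divide="ignore", invalid="ignore"):
        img = np.log2(result.saddle)
    lim = np.nanmax(np.abs(img))
    im = ax.imshow(img, cmap=cmap, vmin=-lim, vmax=lim, origin="upper")
    ax.set_xlabel("eigenvector quantile")
    ax.set_ylabel("eigenvector quantile")
    ax.text(
        0.5, 0.5, f"{result.strength:.2f}", transform=ax.transAxes,
        ha="center", va="center", fontsize=14,
    )
    ax.figure.colorbar(im, ax=ax, label="log2 mean O/E", shrink=0.8)
    return ax
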