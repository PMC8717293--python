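"""Figures for niche comparisons and projection maps (matplotlib, Agg)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .niche import NicheGrid

__all__ = ["plot_niche_comparison", "plot_suitability_map"]


def _density_level(e: np.ndarray, mass: float) -> float:
    """Density level whose superlevel set carries the given mass of e."""
    flat = np.sort(e[e > 0])[::-1]
    csum = np.cumsum(flat)
    idx = np.searchsorted(csum, mass * csum[-1])
    return float(flat[min(idx, len(flat) - 1)])


def plot_niche_comparison(
    native: NicheGrid,
    invasive: NicheGrid,
    path,
    titles=("native range niche", "invasive range niche"),
) -> None:
    """Two-panel occupancy-density figure in the shared PCA-environment
    space, with solid contours around all available climates and dashed
    contours around the 50% most frequent ones."""
    fig, axes = plt.subplots(1, 2, figsize=(11, 5), sharex=True, sharey=True)
    for ax, grid, title in zip(axes, (native, invasive), titles):
        x = grid.axis_centers(0)
        y = grid.axis_centers(1)
        ax.imshow(
            grid.z.T,
            origin="lower",
            extent=(x[0], x[-1], y[0], y[-1]),
            cmap="Greys",
            aspect="auto",
        )
        for g, style in ((native, "-"), (invasive, ":")):
            lev100 = _density_level(g.e, 0.999)
            lev50 = _density_level(g.e, 0.5)
            ax.contour(
                x, y, g.e.T, levels=[lev100], colors="black", linestyles=style,
                linewidths=0.8,
            )
            ax.contour(
                x, y, g.e.T, levels=[lev50], colors="black", linestyles="--",
                linewidths=0.6,
            )
        ax.set_title(title)
        ax.set_xlabel("PC1")
    axes[0].set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_suitability_map(smap, path, cmap="viridis") -> None:
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(smap.values, cmap=cmap, vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label="habitat suitability")
    ax.set_title(f"ensemble suitability ({smap.scenario})")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
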