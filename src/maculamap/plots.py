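"""Figures: correlation heatmap panels, vector maps and box plots.

Every figure has a machine-readable CSV counterpart written by the
pipeline; these functions only render.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .sfmap import CorrelationAtlas, VectorMap


def heatmap_panel(atlas: CorrelationAtlas, path: str | Path) -> Path:
    """One sub-panel per VF unit, placed at its mapped superpixel.

    Each sub-panel is the unit's full correlation map over all
    superpixels (n x n image, diverging scale, -1..1).
    """
    grid = atlas.unit_map.grid
    n = grid.n
    fig, axes = plt.subplots(n, n, figsize=(1.1 * n, 1.1 * n))
    for ax in axes.ravel():
        ax.set_axis_off()
    for u in atlas.unit_map.units:
        row, col = divmod(u.mapped_superpixel - 1, n)
        ax = axes[row, col]
        img = atlas.r.loc[u.id].to_numpy().reshape(n, n)
        ax.imshow(img, cmap="RdBu_r", vmin=-1, vmax=1, interpolation="nearest")
        ax.set_title(u.id, fontsize=5, pad=1)
        ax.set_axis_on()
        ax.set_xticks([])
        ax.set_yticks([])
    fig.suptitle(
        f"{atlas.scheme} {atlas.layer} ({atlas.modality} perimetry), "
        f"n={atlas.n_subjects}",
        fontsize=10,
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def vector_map_figure(vmap: VectorMap, path: str | Path) -> Path:
    """Arrows from each mapped superpixel to its maximum-correlation cell.

    Vector gray level encodes correlation strength (darker = stronger);
    hits are drawn as filled dots.  The horizontal midline is bold.
    """
    grid = vmap.unit_map.grid
    h = grid.half_extent
    fig, ax = plt.subplots(figsize=(6, 6))
    ticks = np.arange(-h, h + 1e-9, grid.cell_size)
    for t in ticks:
        ax.axhline(t, color="0.85", lw=0.6, zorder=0)
        ax.axvline(t, color="0.85", lw=0.6, zorder=0)
    ax.axhline(0.0, color="black", lw=1.8, zorder=1)
    rmaxes = vmap.frame["r_max"].to_numpy()
    lo, hi = np.nanmin(rmaxes), np.nanmax(rmaxes)
    span = hi - lo if hi > lo else 1.0
    for u, rec in zip(vmap.unit_map.units, vmap.frame.itertuples()):
        x0, y0 = grid.cell_center(rec.mapped_superpixel)
        gray = 0.8 - 0.8 * (rec.r_max - lo) / span  # strong -> dark
        if rec.hit:
            ax.plot(x0, y0, "o", color=str(gray), ms=6, zorder=3)
        else:
            x1, y1 = grid.cell_center(rec.target_superpixel)
            ax.annotate(
                "",
                xy=(x1, y1),
                xytext=(x0, y0),
                arrowprops=dict(arrowstyle="->", color=str(gray), lw=1.4),
                zorder=2,
            )
    ax.set_xlim(-h - 1, h + 1)
    ax.set_ylim(-h - 1, h + 1)
    ax.set_aspect("equal")
    ax.set_xlabel("temporal  <-  x (deg)  ->  nasal")
    ax.set_ylabel("inferior  <-  y (deg)  ->  superior")
    ax.set_title(f"{vmap.scheme} {vmap.layer} ({vmap.modality}) vector map")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def boxplot_figure(groups: dict[str, np.ndarray], path: str | Path, title: str = "") -> Path:
    """Quartile box plots of correlation distributions."""
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(groups), 4))
    labels = list(groups)
    ax.boxplot([np.asarray(groups[k], float) for k in labels], tick_labels=labels)
    ax.set_ylabel("max Pearson r")
    if title:
        ax.set_title(title)
    ax.tick_params(axis="x", rotation=30)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
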