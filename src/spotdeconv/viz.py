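"""Spatial visualization of deconvolution results.

Two figure types: a scatter-pie map (one pie glyph per spot, wedge angles
proportional to the spot's estimated composition) and per-type proportion
maps (spots colored by one type's proportion on a fixed [0, 1] scale so
panels are comparable).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Wedge
from scipy.spatial import cKDTree

from .io import CellTypeProportions

__all__ = ["type_colors", "overall_plot", "separate_plot"]


def type_colors(type_names: Sequence[str]) -> dict[str, tuple]:
    """Stable type -> color mapping: a pure function of the sorted name list."""
    names = sorted(str(t) for t in type_names)
    cmap = matplotlib.colormaps["tab20"]
    return {t: cmap(i % 20) for i, t in enumerate(names)}


def _default_radius(coords: np.ndarray) -> float:
    if coords.shape[0] < 2:
        return 0.4
    d, _ = cKDTree(coords).query(coords, k=2)
    nn = d[:, 1]
    nn = nn[nn > 0]
    return 0.4 * float(np.median(nn)) if nn.size else 0.4


def overall_plot(
    P: CellTypeProportions,
    coords: np.ndarray,
    path: str | Path | None = None,
    radius: float | None = None,
    ax: plt.Axes | None = None,
    invert_y: bool = False,
) -> plt.Figure:
    """Scatter-pie map: one pie per spot, wedge angles from its proportions.

    Wedges carry gid ``spot-<i>-type-<name>`` so the composition can be read
    back from the figure. Saves to ``path`` if given (format by extension).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != P.n_spots:
        raise ValueError(
            f"{coords.shape[0]} coordinate rows for {P.n_spots} proportion rows"
        )
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 6))
    else:
        fig = ax.figure
    r = radius if radius is not None else _default_radius(coords)
    colors = type_colors(P.type_names)
    for i in range(P.n_spots):
        theta = 0.0
        for k, t in enumerate(P.type_names.tolist()):
            frac = P.proportions[i, k]
            if frac <= 0:
                continue
            w = Wedge(
                (coords[i, 0], coords[i, 1]),
                r,
                theta,
                theta + 360.0 * frac,
                facecolor=colors[t],
                edgecolor="none",
            )
            w.set_gid(f"spot-{i}-type-{t}")
            ax.add_patch(w)
            theta += 360.0 * frac
    handles = [plt.Line2D([], [], marker="o", ls="", color=colors[t], label=t) for t in sorted(colors)]
    ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.02, 0.5), frameon=False)
    ax.set_xlim(coords[:, 0].min() - 2 * r, coords[:, 0].max() + 2 * r)
    ax.set_ylim(coords[:, 1].min() - 2 * r, coords[:, 1].max() + 2 * r)
    if invert_y:
        ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title("estimated cell-type composition")
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=150)
    return fig


def separate_plot(
    P: CellTypeProportions,
    coords: np.ndarray,
    types: Sequence[str] | None = None,
    path: str | Path | None = None,
    cmap: str = "viridis",
    spot_size: float = 40.0,
    invert_y: bool = False,
) -> plt.Figure:
    """One panel per requested type, spots colored by proportion on [0, 1]."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != P.n_spots:
        raise ValueError(
            f"{coords.shape[0]} coordinate rows for {P.n_spots} proportion rows"
        )
    all_types = P.type_names.tolist()
    if types is None:
        types = all_types
    unknown = [t for t in types if t not in all_types]
    if unknown:
        raise ValueError(f"unknown cell type(s) {unknown}; valid names: {all_types}")
    n = len(types)
    ncols = min(n, 3)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3.5 * nrows), squeeze=False)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    for ax, t in zip(axes.ravel(), types):
        k = all_types.index(t)
        sc = ax.scatter(
            coords[:, 0], coords[:, 1], c=P.proportions[:, k],
            vmin=0.0, vmax=1.0, cmap=cmap, s=spot_size,
        )
        fig.colorbar(sc, ax=ax)
        if invert_y:
            ax.invert_yaxis()
        ax.set_aspect("equal")
        ax.set_title(t)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=150)
    return fig
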