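"""Minimal topographic rendering of channel-wise values."""

from __future__ import annotations

import numpy as np


def plot_topomap(values, positions, path=None, ax=None, title=None, highlight=None):
    """Scatter a per-channel value map on the 2-D projected montage.

    Positions are 3-D unit-sphere points; the azimuthal-equidistant style
    projection drops them to the plane for display. ``highlight`` marks a
    channel-index subset (e.g. a significant cluster) with ring markers.
    Returns the matplotlib axis; writes ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pos = np.asarray(positions, float)
    values = np.asarray(values, float)
    r = np.arccos(np.clip(pos[:, 2], -1, 1))
    theta = np.arctan2(pos[:, 1], pos[:, 0])
    x, y = r * np.cos(theta), r * np.sin(theta)
    if ax is None:
        _fig, ax = plt.subplots(figsize=(4, 4))
    vmax = np.max(np.abs(values)) or 1.0
    sc = ax.scatter(x, y, c=values, cmap="RdBu_r", vmin=-vmax, vmax=vmax, s=120)
    if highlight is not None:
        hi = np.asarray(highlight, int)
        ax.scatter(x[hi], y[hi], facecolors="none", edgecolors="k", s=260, linewidths=1.5)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(sc, ax=ax, shrink=0.7)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=120)
        plt.close(ax.figure)
    return ax
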