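"""Minimal map helper for back-projected province/AEP label layers."""

from __future__ import annotations

import numpy as np


def plot_label_map(grid: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                   path=None, fill: int = -1, ax=None, title: str | None = None):
    """pcolormesh of an integer label layer; fill cells rendered black.

    Returns the matplotlib Axes.  Colours are arbitrary (labels are assigned
    in cluster-discovery order and carry no ecological meaning).
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4.5))
    masked = np.ma.masked_equal(grid, fill)
    cmap = plt.get_cmap("tab20").copy()
    cmap.set_bad("black")
    ax.pcolormesh(lon, lat, masked, cmap=cmap, shading="nearest")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
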