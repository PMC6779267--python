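"""Minimal plotting helpers (grid-search landscapes, robustness curves)."""

from __future__ import annotations

import numpy as np


def plot_landscape(result, x_axis: str = "a", y_axis: str = "G", ax=None):
    """Heatmap of the composite score over two grid axes, minimized over
    the remaining ones."""
    import matplotlib.pyplot as plt

    names = ["a", "G", "lam", "m"]
    land = result.composite.reshape(tuple(len(result.axes[n]) for n in names))
    keep = [names.index(x_axis), names.index(y_axis)]
    other = [i for i in range(4) if i not in keep]
    land2 = land.min(axis=tuple(other))
    if names.index(x_axis) > names.index(y_axis):
        land2 = land2.T
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        land2.T, origin="lower", aspect="auto",
        extent=[
            result.axes[x_axis][0], result.axes[x_axis][-1],
            result.axes[y_axis][0], result.axes[y_axis][-1],
        ],
    )
    ax.set_xlabel(x_axis)
    ax.set_ylabel(y_axis)
    ax.figure.colorbar(im, ax=ax, label="composite score")
    return ax


def plot_robustness(curves, ax=None):
    """Overlay giant-component robustness curves (one per attack strategy)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in np.atleast_1d(curves):
        ax.plot(c.f_grid, c.fraction_in_giant, marker="o", label=c.strategy)
    ax.set_xlabel("fraction of regions perturbed, f")
    ax.set_ylabel("relative giant-component size")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax
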