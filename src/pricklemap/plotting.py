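"""Diagnostic heat maps of density grids on the (phi, h) plane."""

from __future__ import annotations

import numpy as np

from .field import DensityGrid

__all__ = ["plot_density_grid", "plot_fit_comparison"]


def plot_density_grid(grid: DensityGrid, ax=None, title: str | None = None,
                      **imshow_kwargs):
    """Heat map of a density grid; phi in degrees on the x axis, h on y."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = (0.0, 360.0, 0.0, float(grid.t_axis[-1] + grid.t_axis[1]))
    im = ax.imshow(grid.values.T, origin="lower", aspect="auto",
                   extent=extent, **imshow_kwargs)
    ax.set_xlabel(r"$\phi$ (deg)")
    ax.set_ylabel("h")
    ax.set_title(title or grid.kind.value)
    ax.figure.colorbar(im, ax=ax, shrink=0.85)
    return ax


def plot_fit_comparison(observed: DensityGrid, model: DensityGrid, axes=None):
    """Observed KDE and fitted model density side by side."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    plot_density_grid(observed, ax=axes[0], title="observed (KDE)")
    plot_density_grid(model, ax=axes[1], title="model (fitted)")
    return axes
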