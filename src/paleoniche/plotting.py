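"""Simple raster plots of suitability surfaces and classified maps."""

from __future__ import annotations

import numpy as np

from .bioclim import SuitabilitySurface

__all__ = ["plot_surface", "plot_classified"]


def plot_surface(surface: SuitabilitySurface, ax=None, title: str | None = None):
    """Image plot of a suitability surface; masked cells transparent."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    img = ax.imshow(surface.values, vmin=0.0, vmax=1.0, cmap="viridis")
    ax.figure.colorbar(img, ax=ax, label="suitability")
    ax.set_title(title or surface.taxon_or_node)
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    return ax


def plot_classified(surface: SuitabilitySurface, ax=None, title: str | None = None):
    """Three-class map: grey below, yellow = all but one variable, red = all."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    from .bioclim import classify_surface

    if ax is None:
        _, ax = plt.subplots()
    classes = classify_surface(surface).astype(float)
    classes[surface.nodata_mask] = np.nan
    cmap = ListedColormap(["lightgrey", "gold", "red"])
    ax.imshow(classes, cmap=cmap, vmin=0, vmax=2)
    ax.set_title(title or surface.taxon_or_node)
    return ax
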