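"""Ternary-diagram plotting (optional; requires matplotlib at call time).

Compositions are drawn inside the reference triangle with vertices at
(0, 0), (1, 0) and (0.5, sqrt(3)/2), labeled by part name.  These plots are
presentation-only: nothing in the analysis pipeline depends on them.
"""

from __future__ import annotations

import numpy as np

from .inference import ConfidenceRegion, ternary_coords

__all__ = ["ternary_axes", "plot_composition_path", "plot_regions"]

_TRIANGLE = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0], [0.0, 0.0]])


def ternary_axes(labels=("pCSF", "pGM", "pWM"), ax=None):
    """Draw the reference triangle and return the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5.5))
    ax.plot(_TRIANGLE[:, 0], _TRIANGLE[:, 1], color="black", lw=1)
    ax.text(-0.02, -0.02, labels[0], ha="right", va="top")
    ax.text(1.02, -0.02, labels[1], ha="left", va="top")
    ax.text(0.5, np.sqrt(3.0) / 2.0 + 0.02, labels[2], ha="center", va="bottom")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def plot_composition_path(compositions, ax=None, **plot_kwargs):
    """Plot a sequence of compositions as a path in the ternary plane."""
    ax = ternary_axes(ax=ax) if ax is None else ax
    xy = ternary_coords(np.asarray(compositions, dtype=float))
    ax.plot(xy[:, 0], xy[:, 1], **plot_kwargs)
    return ax


def plot_regions(regions: list[ConfidenceRegion], path=None, estimate=None, ax=None):
    """Plot bootstrap confidence regions (dashed contours) at their ages."""
    import matplotlib.pyplot as plt

    ax = ternary_axes(ax=ax)
    for reg in regions:
        for c in reg.contours:
            c = np.asarray(c)
            ax.plot(c[:, 0], c[:, 1], ls="--", lw=1, color="C0")
    if estimate is not None:
        xy = ternary_coords(np.asarray(estimate, dtype=float))
        xy = np.atleast_2d(xy)
        ax.plot(xy[:, 0], xy[:, 1], "o", color="C1", ms=4)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
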