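"""Diagnostic plots: reference ellipses and the zone probability surface."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .microwear import ReferencePopulation
from .wear_seasonality import BoundaryModel


def plot_bivariate(
    references: Mapping[str, ReferencePopulation],
    points: Mapping[str, tuple[float, float]] | None = None,
    ax=None,
):
    """Scratch/pit plane with reference confidence ellipses and sample points."""

    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for diet, pop in references.items():
        major, minor, angle = pop.ellipse.axes
        ax.add_patch(
            Ellipse(
                pop.ellipse.centroid,
                2 * major,
                2 * minor,
                angle=np.degrees(angle),
                fill=False,
                label=f"{diet} (p={pop.ellipse.p:.2f})",
            )
        )
        if pop.points is not None:
            ax.plot(pop.points[:, 0], pop.points[:, 1], ".", alpha=0.5)
    for label, (ns, np_) in (points or {}).items():
        ax.plot(ns, np_, "k^")
        ax.annotate(label, (ns, np_), fontsize=8, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("NS (scratches / 0.16 mm$^2$)")
    ax.set_ylabel("NP (pits / 0.16 mm$^2$)")
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_zone_surface(
    model: BoundaryModel,
    points: Mapping[str, tuple[float, float]] | None = None,
    ax=None,
):
    """Error-probability heat map with the argmax zone boundaries."""

    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    err = 1.0 - model.probabilities.max(axis=0)
    mesh = ax.pcolormesh(model.cv_grid, model.sd_grid, err.T, shading="auto", cmap="magma")
    plt.colorbar(mesh, ax=ax, label="error probability")
    winner = model.probabilities.argmax(axis=0)
    ax.contour(model.cv_grid, model.sd_grid, winner.T, levels=[0.5, 1.5], colors="w")
    for label, (cv, sd) in (points or {}).items():
        ax.plot(cv, sd, "wo", mec="k")
        ax.annotate(label, (cv, sd), fontsize=8, color="w", xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("CV* of NS")
    ax.set_ylabel("SD of NS")
    return ax
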