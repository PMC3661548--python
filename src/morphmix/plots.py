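"""Optional figures: trait histogram with fitted mixture curves, and the
isometric allometry scatter with per-group SMA lines.

Figures are outputs only — no computation reads them.  matplotlib is
imported lazily so the analysis stack works without a plotting backend.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .allometry import GroupAllometry
from .facing_gamma import ClassificationResult, MixtureModel
from .io import MeasurementTable, Sex


def _mpl():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_mixture_histogram(xs, model: MixtureModel, path: str,
                           bins: int = 18) -> None:
    """Histogram of the male trait overlaid with the two component curves."""
    plt = _mpl()
    xs = np.asarray(xs, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(xs, bins=bins, color="0.8", edgecolor="0.3", density=False)
    ax2 = ax.twinx()
    grid = np.linspace(model.homeo.bound, model.hetero.bound, 400)
    ax2.plot(grid, 100 * model.weight_homeo * model.homeo.pdf(grid),
             "k--", label="homeomorphic")
    ax2.plot(grid, 100 * (1 - model.weight_homeo) * model.hetero.pdf(grid),
             "k-", label="heteromorphic")
    ax.set_xlabel("pedipalpal patella length (mm)")
    ax.set_ylabel("frequency")
    ax2.set_ylabel("predicted probability (%)")
    ax2.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_allometry(table: MeasurementTable,
                   classification: Optional[ClassificationResult],
                   groups: GroupAllometry, path: str) -> None:
    """Isometric scatter (equal axis increments) with per-group SMA lines."""
    plt = _mpl()
    adults = table.adults()
    males = [r for r in adults if r.sex is Sex.MALE and r.usable]
    females = [r for r in adults if r.sex is Sex.FEMALE and r.usable]

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    styles = {"heteromorphic": dict(marker="o", c="k"),
              "homeomorphic": dict(marker="o", facecolors="none", edgecolors="k"),
              "unassigned": dict(marker="o", c="0.6")}
    if classification is not None:
        for rec, lab in zip(males, classification.labels):
            ax.scatter(rec.prosoma_length, rec.patella_length, s=25,
                       **styles[lab])
    else:
        for rec in males:
            ax.scatter(rec.prosoma_length, rec.patella_length, s=25, c="0.4")
    for rec in females:
        ax.scatter(rec.prosoma_length, rec.patella_length, s=30, marker="+",
                   c="k")

    dash = {"heteromorphic males": "-", "homeomorphic males": "--",
            "females": ":"}
    xs_all = [r.prosoma_length for r in males + females]
    for name, fit in groups.fits.items():
        gx = np.linspace(min(xs_all), max(xs_all), 2)
        ax.plot(gx, fit.intercept + fit.slope * gx, "k" + dash.get(name, "-"),
                lw=1, label=name)
    ax.set_xlabel("prosoma length (mm)")
    ax.set_ylabel("pedipalpal patella length (mm)")
    ax.set_aspect("equal")  # isometric axes: equal mm increments
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
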