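"""Diagnostic plots: module vs background in the 2-D statistic space.

Rendering is deliberately separated from :func:`mdgsa.pipeline.ellipse_summary`
so the statistical summary stays testable without a display.
"""

from __future__ import annotations

import numpy as np

from .geneset_io import GeneSetCollection, membership_vector
from .pipeline import ellipse_summary
from .rankings import GeneRanking

__all__ = ["plot_set"]


def plot_set(
    ranking: GeneRanking,
    coll: GeneSetCollection,
    set_id: str,
    level: float = 0.95,
    ax=None,
):
    """Scatter all genes in (X, Y) and highlight one module.

    Blue cross-hairs and ellipse summarise all genes; red ones summarise the
    module's genes.  The red ellipse's orientation shows the trend of the
    relationship between the two statistics inside the module.
    """
    import matplotlib.pyplot as plt

    if ranking.n_dims != 2:
        raise ValueError("plot_set requires a 2-dimensional ranking")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    mv = membership_vector(coll, set_id, ranking.universe)
    member = mv.indicator.astype(bool)
    pts = ranking.values
    ax.scatter(pts[:, 0], pts[:, 1], s=4, c="lightgrey", linewidths=0, zorder=1)
    ax.scatter(
        pts[member, 0], pts[member, 1], s=12, c="red", linewidths=0, zorder=3
    )
    for subset, colour in ((np.ones(len(pts), bool), "blue"), (member, "red")):
        summ = ellipse_summary(pts[subset], level=level)
        ax.axvline(summ.mean[0], color=colour, lw=0.8, alpha=0.6, zorder=2)
        ax.axhline(summ.mean[1], color=colour, lw=0.8, alpha=0.6, zorder=2)
        if not summ.degenerate:
            boundary = summ.boundary()
            ax.plot(boundary[:, 0], boundary[:, 1], color=colour, lw=1.5, zorder=4)
    ax.set_xlabel(ranking.dimension_names[0])
    ax.set_ylabel(ranking.dimension_names[1])
    ax.set_title(f"{set_id} {coll.description(set_id)}".strip())
    return ax
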