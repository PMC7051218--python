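"""Figure rendering for the report bundle.

Figures are artifacts only; no downstream number is ever read back from a
rendered image.  Color conventions: occupancy heatmaps use blue for
proteins in every replicate, grey for intermediate occupancy and red for
singletons; abundance heatmaps use a diverging scale with dark red for the
most abundant proteins and dark blue for the least.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap, LogNorm
from matplotlib.patches import Circle

from .qualitative import PresenceMatrix, VennPartition
from .quantitative import AbundanceRanking

__all__ = ["occupancy_heatmap", "venn_figure", "abundance_heatmap"]


def occupancy_heatmap(presence: PresenceMatrix, path: str | Path) -> Path:
    """Presence/absence heatmap with rows sorted by decreasing occupancy and
    colored by occupancy class (blue all / grey intermediate / red singleton)."""
    path = Path(path)
    occ = presence.present.sum(axis=1)
    keep = occ >= 1
    mat = presence.present[keep]
    occ = occ[keep]
    order = np.argsort(-occ, kind="stable")
    mat, occ = mat[order], occ[order]
    n_reps = presence.n_replicates
    # class code per cell: 0 absent, then 1 singleton / 2 intermediate / 3 all
    cls = np.where(occ == n_reps, 3, np.where(occ == 1, 1, 2))
    img = mat * cls[:, None]
    cmap = ListedColormap(["white", "#c0392b", "#95a5a6", "#2a5db0"])
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(img, aspect="auto", interpolation="nearest", cmap=cmap, vmin=0, vmax=3)
    ax.set_xticks(range(n_reps), presence.replicate_ids, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{mat.shape[0]} proteins (decreasing occupancy)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def venn_figure(partition: VennPartition, path: str | Path) -> Path:
    """Three-circle Venn sketch per triad annotated with the collapsed
    unique / shared-by-2 / common-to-3 counts, plus the triad averages."""
    path = Path(path)
    triads = list(partition.per_triad)
    fig, axes = plt.subplots(1, len(triads) + 1, figsize=(3.2 * (len(triads) + 1), 3.2))
    centers = [(-0.35, 0.25), (0.35, 0.25), (0.0, -0.4)]
    colors = ["#e8638c", "#f3c614", "#2a5db0"]
    panels = triads + [
        {
            "group": f"{partition.scheme.value} average",
            "unique_to_one": partition.averages["unique_to_one"],
            "shared_by_exactly_two": partition.averages["shared_by_exactly_two"],
            "common_to_three": partition.averages["common_to_three"],
        }
    ]
    for ax, triad in zip(np.atleast_1d(axes), panels):
        for (cx, cy), color in zip(centers, colors):
            ax.add_patch(Circle((cx, cy), 0.62, alpha=0.35, color=color))
        ax.text(0, 0.02, f"{triad['common_to_three']:g}", ha="center", fontsize=11)
        ax.text(
            0,
            -1.25,
            f"unique {triad['unique_to_one']:g} | shared-2 {triad['shared_by_exactly_two']:g}",
            ha="center",
            fontsize=8,
        )
        ax.set_title(str(triad["group"]), fontsize=10)
        ax.set_xlim(-1.4, 1.4)
        ax.set_ylim(-1.5, 1.3)
        ax.set_aspect("equal")
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def abundance_heatmap(ranking: AbundanceRanking, path: str | Path) -> Path:
    """Log-scaled abundance heatmap of the ranked proteins, columns in the
    grouping's order; dark red = most abundant, dark blue = least."""
    path = Path(path)
    vals = np.asarray(ranking.values, dtype=float)
    positive = vals[vals > 0]
    floor = positive.min() if positive.size else 1.0
    vals = np.where(vals > 0, vals, floor)
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(
        vals,
        aspect="auto",
        interpolation="nearest",
        cmap="RdBu_r",
        norm=LogNorm(vmin=floor, vmax=vals.max()),
    )
    ax.set_xticks(range(len(ranking.replicate_order)), ranking.replicate_order, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{vals.shape[0]} proteins (decreasing pooled abundance)")
    fig.colorbar(im, ax=ax, shrink=0.6, label="abundance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
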