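"""Figure helpers for the projected conformational space.

Every figure here visualizes a table the pipeline also writes as plain
text; plotting is presentation only and carries no statistics of its own.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .landscape import GridOccupancy, relative_fraction_map
from .projection import Projection

__all__ = [
    "scatter_by_observable",
    "scatter_by_label",
    "fraction_map_figure",
    "density_figure",
    "sector_overlay_figure",
    "contact_map_figure",
]


def scatter_by_observable(proj: Projection, values, path, label: str = "observable") -> None:
    """Projection scatter colored by a per-conformation observable (e.g. Rg)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(proj.coords[:, 0], proj.coords[:, 1], c=values, s=4, cmap="viridis")
    fig.colorbar(sc, ax=ax, label=label)
    ax.set_xlabel("projection x")
    ax.set_ylabel("projection y")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scatter_by_label(proj: Projection, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    labels = proj.labels if proj.labels is not None else np.repeat("all", proj.n_points)
    for lab in dict.fromkeys(labels.tolist()):
        pts = proj.coords[labels == lab]
        ax.scatter(pts[:, 0], pts[:, 1], s=4, label=str(lab), alpha=0.6)
    ax.legend(markerscale=3, fontsize=8)
    ax.set_xlabel("projection x")
    ax.set_ylabel("projection y")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fraction_map_figure(occ: GridOccupancy, model: str, proj: Projection, path) -> None:
    """Relative-fraction surface of one model over the gray point cloud."""
    F = relative_fraction_map(occ, model)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(proj.coords[:, 0], proj.coords[:, 1], c="0.8", s=3)
    mesh = ax.pcolormesh(
        occ.x_edges, occ.y_edges, np.ma.masked_invalid(F).T,
        cmap="YlOrRd", vmin=0.0, vmax=1.0, alpha=0.75,
    )
    fig.colorbar(mesh, ax=ax, label=f"relative fraction ({model})")
    ax.set_xlabel("projection x")
    ax.set_ylabel("projection y")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def density_figure(proj: Projection, density, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    order = np.argsort(density)  # draw densest on top
    sc = ax.scatter(
        proj.coords[order, 0], proj.coords[order, 1], c=density[order], s=4, cmap="magma"
    )
    fig.colorbar(sc, ax=ax, label="KDE density")
    ax.set_xlabel("projection x")
    ax.set_ylabel("projection y")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def sector_overlay_figure(proj: Projection, sector_indices: dict[int, np.ndarray], path) -> None:
    """Per-sector point subsets in distinct colors over the gray cloud."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(proj.coords[:, 0], proj.coords[:, 1], c="0.85", s=3)
    cmap = plt.get_cmap("tab10")
    for sector, idx in sorted(sector_indices.items()):
        ax.scatter(
            proj.coords[idx, 0], proj.coords[idx, 1],
            s=5, color=cmap(sector % 10), label=f"sector {sector}", alpha=0.7,
        )
    ax.legend(markerscale=3, fontsize=8)
    ax.set_xlabel("projection x")
    ax.set_ylabel("projection y")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def contact_map_figure(contacts: np.ndarray, path, title: str = "contact frequency") -> None:
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(contacts, origin="lower", cmap="Blues", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label=title)
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
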