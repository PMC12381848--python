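"""Local Conformational Signatures (LCS).

An LCS characterizes a region of the projected conformational space by the
conformation that minimizes the average distance-RMSD over the selected
region (the medoid), displayed together with its n closest neighbors by
distance-RMSD, and summarized by a Cα contact-frequency map over the
members.  Distance-RMSD, like Q_w, is computed on internal distances only
and therefore needs no superposition:

    dRMSD(k, l) = sqrt( (1/N_p) Σ_{i<j} (r_ij^k − r_ij^l)² )
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dissimilarity import internal_distances, pair_indices
from .ensembles import PooledSet
from .projection import Projection

__all__ = [
    "RegionSelection",
    "LCSResult",
    "distance_rmsd",
    "distance_rmsd_matrix",
    "extract_lcs",
    "contact_map",
    "DEFAULT_N_NEIGHBORS",
    "DEFAULT_CONTACT_CUTOFF",
]

DEFAULT_N_NEIGHBORS = 30  # per-figure convention for short-tail systems; 20 for long chains
DEFAULT_CONTACT_CUTOFF = 8.0  # Å Cα–Cα


@dataclass(frozen=True)
class RegionSelection:
    """A region of the projection resolved to conformation indices.

    Exactly one of the three mechanisms applies:

    * ``indices`` — explicit conformation index list;
    * ``polygon`` — vertices in projection coordinates (points inside are
      selected);
    * ``radius`` — disc of this radius around the densest projected point
      ("top-density" seeding); requires a density track.
    """

    indices: tuple[int, ...] | None = None
    polygon: tuple[tuple[float, float], ...] | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        given = sum(x is not None for x in (self.indices, self.polygon, self.radius))
        if given != 1:
            raise ValueError("specify exactly one of indices, polygon, or radius")

    def resolve(
        self, proj: Projection | None = None, density: np.ndarray | None = None
    ) -> np.ndarray:
        if self.indices is not None:
            idx = np.asarray(self.indices, dtype=np.int64)
        elif self.polygon is not None:
            if proj is None:
                raise ValueError("polygon selection needs a projection")
            from matplotlib.path import Path

            idx = np.flatnonzero(Path(np.asarray(self.polygon)).contains_points(proj.coords))
        else:
            if proj is None or density is None:
                raise ValueError("top-density selection needs a projection and a density track")
            center = proj.coords[int(np.argmax(density))]
            d = np.linalg.norm(proj.coords - center, axis=1)
            idx = np.flatnonzero(d <= self.radius)
        if idx.size < 2:
            raise ValueError(f"region resolves to {idx.size} conformations; need at least 2")
        return idx


@dataclass
class LCSResult:
    """The medoid of a selected region with its closest neighbors."""

    medoid_index: int  # global conformation index
    neighbor_indices: np.ndarray  # global indices, nearest first
    selection_indices: np.ndarray
    mean_drmsd: float  # Å, medoid to the whole selection
    neighbor_drmsd: np.ndarray  # Å, medoid to each neighbor
    contacts: np.ndarray  # (R, R) contact frequency over medoid + neighbors

    @property
    def member_indices(self) -> np.ndarray:
        return np.concatenate([[self.medoid_index], self.neighbor_indices])

    def write(self, path, labels: np.ndarray | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("index\trole\tlabel\tdrmsd_to_medoid\n")
            lab = labels[self.medoid_index] if labels is not None else "-"
            fh.write(f"{self.medoid_index}\tmedoid\t{lab}\t0.0\n")
            for i, d in zip(self.neighbor_indices, self.neighbor_drmsd):
                lab = labels[i] if labels is not None else "-"
                fh.write(f"{i}\tneighbor\t{lab}\t{d:.6f}\n")


def distance_rmsd(conf_k: np.ndarray, conf_l: np.ndarray, exclude_adjacent: bool = False) -> float:
    """Root-mean-square deviation of internal Cα–Cα distances, in Å."""
    conf_k = np.asarray(conf_k, dtype=np.float64)
    conf_l = np.asarray(conf_l, dtype=np.float64)
    if conf_k.shape != conf_l.shape:
        raise ValueError(f"size mismatch: {conf_k.shape} vs {conf_l.shape}")
    dk = internal_distances(conf_k, exclude_adjacent)
    dl = internal_distances(conf_l, exclude_adjacent)
    return float(np.sqrt(np.mean((dk - dl) ** 2)))


def distance_rmsd_matrix(xyz: np.ndarray, exclude_adjacent: bool = False) -> np.ndarray:
    """Symmetric dRMSD matrix over a conformation stack (M, R, 3)."""
    d = internal_distances(np.asarray(xyz, dtype=np.float64), exclude_adjacent)
    m = d.shape[0]
    out = np.zeros((m, m))
    for k in range(m - 1):
        diff = d[k + 1 :] - d[k]
        out[k, k + 1 :] = np.sqrt(np.mean(diff * diff, axis=1))
        out[k + 1 :, k] = out[k, k + 1 :]
    return out


def contact_map(conformations: np.ndarray, cutoff: float = DEFAULT_CONTACT_CUTOFF) -> np.ndarray:
    """Per-pair contact frequency: fraction of members with r_ij <= cutoff.

    Returns a symmetric (R, R) matrix; the diagonal is set to 1 by
    convention (a residue always contacts itself).
    """
    xyz = np.asarray(conformations, dtype=np.float64)
    if xyz.ndim == 2:
        xyz = xyz[None]
    if xyz.shape[0] < 1:
        raise ValueError("need at least one conformation")
    n_res = xyz.shape[1]
    iu, ju = pair_indices(n_res)
    d = internal_distances(xyz)
    freq = np.mean(d <= cutoff, axis=0)
    out = np.zeros((n_res, n_res))
    out[iu, ju] = freq
    out[ju, iu] = freq
    np.fill_diagonal(out, 1.0)
    return out


def extract_lcs(
    pooled: PooledSet,
    selection: RegionSelection | np.ndarray,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    proj: Projection | None = None,
    density: np.ndarray | None = None,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    exclude_adjacent: bool = False,
) -> LCSResult:
    """Extract the LCS of a selected projection region.

    The medoid is found exhaustively over the selection (argmin of mean
    dRMSD to all other selected conformations, ties broken by lowest global
    index); its ``n_neighbors`` nearest selected conformations by dRMSD form
    the signature, summarized by a contact map over medoid + neighbors.
    """
    if isinstance(selection, RegionSelection):
        idx = selection.resolve(proj, density)
    else:
        idx = np.asarray(selection, dtype=np.int64)
    idx = np.sort(idx)  # ascending, so the first argmin is the lowest global index
    if idx.size < 2:
        raise ValueError("selection must contain at least 2 conformations")
    if n_neighbors >= idx.size:
        raise ValueError(
            f"n_neighbors={n_neighbors} must be smaller than the selection size {idx.size}"
        )
    sub = pooled.xyz[idx]
    dmat = distance_rmsd_matrix(sub, exclude_adjacent)
    mean_d = dmat.sum(axis=1) / (idx.size - 1)
    medoid_local = int(np.argmin(mean_d))  # argmin takes the first minimum: lowest index
    order = np.argsort(dmat[medoid_local], kind="stable")
    order = order[order != medoid_local][:n_neighbors]
    members = np.concatenate([[idx[medoid_local]], idx[order]])
    return LCSResult(
        medoid_index=int(idx[medoid_local]),
        neighbor_indices=idx[order],
        selection_indices=idx,
        mean_drmsd=float(mean_d[medoid_local]),
        neighbor_drmsd=dmat[medoid_local, order],
        contacts=contact_map(pooled.xyz[members], contact_cutoff),
    )
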