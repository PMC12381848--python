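"""Grid-based differential statistics over a shared 2D projection.

All compared models live in one projected conformational space; a regular
grid (default 27 × 27) over the pooled bounding box turns the point clouds
into per-model occupancy counts, from which three comparison statistics
follow:

* relative fraction  F_ij^w = n_ij^w / N_ij — the occupancy proportion of
  model w in bin (i, j); bins where F = 1 are exclusively populated.
* density overlap    O^{w,z} = Σ_ij f_ij^w f_ij^z with f^w the L2-normalized
  relative-fraction surface — a cosine similarity in [0, 1] that is 1 for
  identical surfaces and 0 for disjoint supports.
* projection entropy H^w = −Σ_ij p_ij^w ln p_ij^w with p_ij^w = n_ij^w / N^w,
  normalized by H_max = ln(number of bins) — a heterogeneity proxy.

Bins with poor statistics (total count below ``min_count``) are masked
invalid for the fraction and overlap statistics to avoid border artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gaussian_kde

from .projection import Projection

__all__ = [
    "GridOccupancy",
    "bin_projection",
    "relative_fraction_map",
    "density_overlap",
    "overlap_table",
    "overlap_uncertainty",
    "projection_entropy",
    "entropy_across_replicates",
    "kde_density",
    "exclusive_regions",
    "exclusive_coverage",
    "DEFAULT_GRID",
    "DEFAULT_MIN_COUNT",
]

DEFAULT_GRID = (27, 27)
DEFAULT_MIN_COUNT = 3


@dataclass
class GridOccupancy:
    """Per-bin, per-model occupancy of a projection on a regular grid."""

    counts: dict[str, np.ndarray]  # label -> (nx, ny) integer counts
    totals: np.ndarray  # (nx, ny) pooled counts N_ij
    valid: np.ndarray  # (nx, ny) bool, totals >= min_count
    x_edges: np.ndarray
    y_edges: np.ndarray
    min_count: int

    @property
    def labels(self) -> list[str]:
        return list(self.counts.keys())

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.totals.shape

    @property
    def n_bins(self) -> int:
        return int(np.prod(self.totals.shape))

    def bin_index(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Bin (ix, iy) of each 2D point; right/top edge inclusive."""
        coords = np.atleast_2d(coords)
        nx, ny = self.grid_shape
        ix = np.clip(np.searchsorted(self.x_edges, coords[:, 0], side="right") - 1, 0, nx - 1)
        iy = np.clip(np.searchsorted(self.y_edges, coords[:, 1], side="right") - 1, 0, ny - 1)
        return ix, iy


def bin_projection(
    proj: Projection,
    grid: tuple[int, int] = DEFAULT_GRID,
    min_count: int = DEFAULT_MIN_COUNT,
) -> GridOccupancy:
    """Histogram a labeled projection on a regular grid over its bounding box.

    Bins are half-open except the final edge (right/top inclusive), so every
    point is binned exactly once.  Bins with pooled count below ``min_count``
    are masked invalid ("poor statistics").
    """
    if proj.n_points == 0:
        raise ValueError("projection is empty")
    if proj.labels is None:
        labels = np.repeat("all", proj.n_points)
    else:
        labels = proj.labels
    lo = proj.coords.min(axis=0)
    hi = proj.coords.max(axis=0)
    if np.any(hi - lo <= 0):
        raise ValueError("degenerate bounding box: all points coincide along an axis")
    x_edges = np.linspace(lo[0], hi[0], grid[0] + 1)
    y_edges = np.linspace(lo[1], hi[1], grid[1] + 1)
    counts: dict[str, np.ndarray] = {}
    for lab in dict.fromkeys(labels.tolist()):  # preserve first-seen order
        pts = proj.coords[labels == lab]
        h, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[x_edges, y_edges])
        counts[str(lab)] = h.astype(np.int64)
    totals = np.sum(list(counts.values()), axis=0)
    return GridOccupancy(
        counts=counts,
        totals=totals,
        valid=totals >= min_count,
        x_edges=x_edges,
        y_edges=y_edges,
        min_count=min_count,
    )


def relative_fraction_map(occ: GridOccupancy, model: str) -> np.ndarray:
    """F_ij^w = n_ij^w / N_ij on valid occupied bins; NaN elsewhere."""
    if model not in occ.counts:
        raise KeyError(f"unknown model label {model!r}")
    F = np.full(occ.grid_shape, np.nan)
    ok = occ.valid & (occ.totals > 0)
    F[ok] = occ.counts[model][ok] / occ.totals[ok]
    return F


def _normalized_density(occ: GridOccupancy, model: str) -> np.ndarray:
    """L2-normalized relative-fraction surface f^w over valid bins, flat."""
    F = relative_fraction_map(occ, model)
    f = np.nan_to_num(F[occ.valid], nan=0.0)
    norm = np.sqrt(np.sum(f * f))
    if norm == 0.0:
        raise ValueError(f"model {model!r} has no mass on valid bins; overlap undefined")
    return f / norm


def density_overlap(occ: GridOccupancy, w: str, z: str) -> float:
    """Cosine overlap O^{w,z} of two models' normalized density surfaces."""
    return float(np.dot(_normalized_density(occ, w), _normalized_density(occ, z)))


def overlap_table(occ: GridOccupancy) -> pd.DataFrame:
    """Symmetric overlap matrix over all model pairs (unit diagonal)."""
    labs = occ.labels
    dens = {lab: _normalized_density(occ, lab) for lab in labs}
    out = pd.DataFrame(np.eye(len(labs)), index=labs, columns=labs)
    for a in range(len(labs)):
        for b in range(a + 1, len(labs)):
            o = float(np.dot(dens[labs[a]], dens[labs[b]]))
            out.iloc[a, b] = out.iloc[b, a] = o
    return out


def overlap_uncertainty(
    proj: Projection,
    grid: tuple[int, int] = DEFAULT_GRID,
    min_count: int = DEFAULT_MIN_COUNT,
    n_boot: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bootstrap standard errors for the overlap matrix.

    Conformations are resampled with replacement within each model; the grid
    edges are held fixed at the full projection's bounding box so resampled
    occupancies are directly comparable.  Returns (point estimate, std).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if proj.labels is None:
        raise ValueError("overlap uncertainty requires a labeled projection")
    occ0 = bin_projection(proj, grid, min_count)
    point = overlap_table(occ0)
    labs = point.index.tolist()
    rng = np.random.default_rng(seed)
    samples = np.empty((n_boot, len(labs), len(labs)))
    per_model = {lab: np.flatnonzero(proj.labels == lab) for lab in labs}
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx, size=idx.size, replace=True) for idx in per_model.values()]
        )
        boot = Projection(coords=proj.coords[take], labels=proj.labels[take])
        occ = GridOccupancy(
            counts={},
            totals=np.zeros(grid, dtype=np.int64),
            valid=np.zeros(grid, dtype=bool),
            x_edges=occ0.x_edges,
            y_edges=occ0.y_edges,
            min_count=min_count,
        )
        counts = {}
        for lab in labs:
            pts = boot.coords[boot.labels == lab]
            h, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[occ0.x_edges, occ0.y_edges])
            counts[lab] = h.astype(np.int64)
        occ.counts = counts
        occ.totals = np.sum(list(counts.values()), axis=0)
        occ.valid = occ.totals >= min_count
        samples[b] = overlap_table(occ).to_numpy()
    std = pd.DataFrame(samples.std(axis=0, ddof=1), index=labs, columns=labs)
    return point, std


def projection_entropy(
    occ: GridOccupancy, model: str, valid_only: bool = False
) -> dict[str, float]:
    """Shannon entropy of one model's bin-occupancy distribution.

    p_ij^w = n_ij^w / N^w over occupied bins (0·ln 0 ≡ 0); H_max = ln(total
    bin count).  The poor-statistics mask is not applied by default — the
    entropy is a property of the model's own distribution — but can be
    enabled with ``valid_only``.
    """
    if model not in occ.counts:
        raise KeyError(f"unknown model label {model!r}")
    n = occ.counts[model].astype(np.float64)
    if valid_only:
        n = np.where(occ.valid, n, 0.0)
    total = n.sum()
    if total <= 0:
        raise ValueError(f"model {model!r} has no conformations")
    p = n[n > 0] / total
    h = float(-np.sum(p * np.log(p)))
    h_max = float(np.log(occ.n_bins))
    return {
        "entropy": h,
        "h_max": h_max,
        "normalized": h / h_max,
        "n_conformations": int(total),
    }


def entropy_across_replicates(
    projections: list[Projection],
    grid: tuple[int, int] = DEFAULT_GRID,
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.DataFrame:
    """Mean ± std of normalized projection entropy per model over replicates.

    Each replicate projection is binned on its own bounding box (layouts are
    only defined up to rigid/reflective noise), and per-model normalized
    entropies are aggregated.
    """
    if len(projections) < 2:
        raise ValueError("need at least 2 replicate projections")
    ref_labels = None
    rows: dict[str, list[float]] = {}
    for proj in projections:
        occ = bin_projection(proj, grid, min_count)
        labs = tuple(occ.labels)
        if ref_labels is None:
            ref_labels = labs
            rows = {lab: [] for lab in labs}
        elif set(labs) != set(ref_labels):
            raise ValueError("replicate projections carry inconsistent model labels")
        for lab in ref_labels:
            rows[lab].append(projection_entropy(occ, lab)["normalized"])
    table = pd.DataFrame(
        {
            "mean_normalized_entropy": {lab: float(np.mean(v)) for lab, v in rows.items()},
            "std_normalized_entropy": {lab: float(np.std(v, ddof=1)) for lab, v in rows.items()},
            "n_replicates": {lab: len(v) for lab, v in rows.items()},
        }
    )
    table.index.name = "model"
    return table


def kde_density(
    proj: Projection | np.ndarray, bandwidth: float | str | None = None
) -> np.ndarray:
    """Gaussian kernel density estimate evaluated at every projected point.

    ``bandwidth`` follows ``scipy.stats.gaussian_kde`` (Scott's rule by
    default).  Used to rank high-density regions, e.g. for LCS seeding.
    """
    coords = proj.coords if isinstance(proj, Projection) else np.asarray(proj, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("KDE needs at least 2 points")
    try:
        kde = gaussian_kde(coords.T, bw_method=bandwidth)
    except np.linalg.LinAlgError as exc:
        raise ValueError("KDE undefined for a zero-variance point cloud") from exc
    return kde(coords.T)


def exclusive_regions(
    occ: GridOccupancy, model: str, threshold: float = 1.0
) -> tuple[np.ndarray, int]:
    """Connected components of valid bins exclusively populated by ``model``.

    Returns (component label map, number of components); bins count as
    exclusive when F >= threshold (default: relative fraction exactly 1).
    """
    F = relative_fraction_map(occ, model)
    mask = np.nan_to_num(F, nan=0.0) >= threshold
    labeled, n_comp = ndimage.label(mask)
    return labeled, int(n_comp)


def exclusive_coverage(
    occ: GridOccupancy, proj: Projection, model: str, threshold: float = 1.0
) -> float:
    """Fraction of a model's conformations lying in its exclusive bins."""
    if proj.labels is None:
        raise ValueError("labeled projection required")
    labeled, _ = exclusive_regions(occ, model, threshold)
    pts = proj.coords[proj.labels == model]
    if pts.shape[0] == 0:
        raise ValueError(f"model {model!r} has no points")
    ix, iy = occ.bin_index(pts)
    return float(np.mean(labeled[ix, iy] > 0))
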