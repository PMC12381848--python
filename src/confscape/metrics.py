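"""Per-conformation scalar observables for coloring and interpreting projections."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .projection import Projection

__all__ = ["radius_of_gyration", "smoothness_score", "write_observable_track"]


def radius_of_gyration(xyz: np.ndarray) -> float | np.ndarray:
    """Radius of gyration with uniform masses, in Å.

    Rg = sqrt( (1/n) Σ_i |r_i − r_cm|² ).  Accepts one conformation (R, 3)
    or a stack (N, R, 3); uniform bead masses are used throughout because
    the input is a Cα-only coarse-grained model.
    """
    xyz = np.asarray(xyz, dtype=np.float64)
    single = xyz.ndim == 2
    if single:
        xyz = xyz[None]
    if xyz.shape[1] < 2:
        raise ValueError("radius of gyration needs at least 2 beads")
    centered = xyz - xyz.mean(axis=1, keepdims=True)
    rg = np.sqrt(np.mean(np.sum(centered**2, axis=-1), axis=-1))
    return float(rg[0]) if single else rg


def smoothness_score(proj: Projection, track: np.ndarray, k: int = 10) -> float:
    """How smoothly an observable varies over the projected space.

    For each projected point, the absolute difference between its track
    value and the mean over its ``k`` nearest planar neighbors is computed;
    the mean of these is normalized by the track's mean absolute deviation
    about its overall mean.  A spatially smooth observable scores near 0; a
    randomly scattered one scores near 1 (slightly above, by the sampling
    variance of the k-neighbor mean).  Scale- and offset-invariant.
    """
    values = np.asarray(track, dtype=np.float64)
    if values.shape != (proj.n_points,):
        raise ValueError("track must provide one value per projected point")
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, proj.n_points - 1)
    spread = np.mean(np.abs(values - values.mean()))
    if spread == 0.0:
        return 0.0
    tree = cKDTree(proj.coords)
    _, nbr = tree.query(proj.coords, k=k + 1)  # first neighbor is the point itself
    local_mean = values[nbr[:, 1:]].mean(axis=1)
    return float(np.mean(np.abs(values - local_mean)) / spread)


def write_observable_track(name: str, values: np.ndarray, path) -> None:
    """Write (global index, value) as two-column tab-separated text."""
    with open(path, "w") as fh:
        fh.write(f"index\t{name}\n")
        for i, v in enumerate(values):
            fh.write(f"{i}\t{v:.6f}\n")
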