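"""Force-scheme 2D embedding of a dissimilarity matrix.

The force scheme lays out one 2D point per conformation and iteratively
moves every point toward or away from every other so that planar distances
approach the dissimilarities δ(k, l).  Each sweep visits the points in a
random order; with the anchor point p fixed, every other point q is
displaced along the line p→q by a learning-rate fraction of the residual
(d2D(p, q) − δ(p, q)).  The learning rate decays linearly over sweeps, so
the layout anneals from coarse global arrangement to fine refinement.

Runs are reproducible by seed; replicate projections with independent seeds
quantify the layout noise inherent to the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .dissimilarity import validate_dissimilarity

__all__ = ["Projection", "force_scheme", "replicate_projections", "stress"]

_EPS = 1e-9  # guard against coincident points

try:  # numba gives a ~50x faster sweep kernel; the numpy path is equivalent
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _sweeps_numpy(coords: np.ndarray, delta: np.ndarray, orders: np.ndarray, lrs: np.ndarray) -> None:
    n = coords.shape[0]
    for it in range(orders.shape[0]):
        lr = lrs[it]
        for p in orders[it]:
            v = coords - coords[p]
            d = np.sqrt(v[:, 0] ** 2 + v[:, 1] ** 2)
            move = lr * (delta[p] - d) / np.maximum(d, _EPS)
            move[p] = 0.0
            coords += move[:, None] * v


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _sweeps_numba(coords, delta, orders, lrs):  # pragma: no cover - jitted
        n = coords.shape[0]
        for it in range(orders.shape[0]):
            lr = lrs[it]
            for oi in range(n):
                p = orders[it, oi]
                xp = coords[p, 0]
                yp = coords[p, 1]
                for q in range(n):
                    if q == p:
                        continue
                    vx = coords[q, 0] - xp
                    vy = coords[q, 1] - yp
                    d = np.sqrt(vx * vx + vy * vy)
                    dd = d if d > _EPS else _EPS
                    m = lr * (delta[p, q] - d) / dd
                    coords[q, 0] += m * vx
                    coords[q, 1] += m * vy

    _sweeps = _sweeps_numba
else:  # pragma: no cover
    _sweeps = _sweeps_numpy


@dataclass
class Projection:
    """2D embedding of a pooled conformation set (coordinates are unitless)."""

    coords: np.ndarray  # (N, 2)
    labels: np.ndarray | None = None  # per-point model label
    source_indices: np.ndarray | None = None
    seed: int = 0
    n_iterations: int = 0
    stress_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (N, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("projection coordinates must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.coords):
                raise ValueError("one label per projected point required")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def final_stress(self) -> float:
        return float(self.stress_history[-1]) if self.stress_history.size else float("nan")

    def write(self, path) -> None:
        """Write (index, label, x, y, source frame) as tab-separated text."""
        labels = self.labels if self.labels is not None else np.repeat("-", self.n_points)
        src = (
            self.source_indices
            if self.source_indices is not None
            else np.arange(self.n_points)
        )
        with open(path, "w") as fh:
            fh.write("index\tlabel\tx\ty\tsource_frame\n")
            for i in range(self.n_points):
                x, y = self.coords[i]
                fh.write(f"{i}\t{labels[i]}\t{x:.8f}\t{y:.8f}\t{src[i]}\n")


def stress(coords: np.ndarray, delta: np.ndarray) -> float:
    """Residual stress Σ_{k<l} (d2D(k,l) − δ(k,l))²."""
    d2 = pdist(coords)
    return float(np.sum((d2 - squareform(delta, checks=False)) ** 2))


def force_scheme(
    delta: np.ndarray,
    seed: int = 0,
    max_iter: int = 100,
    learning_rate: tuple[float, float] = (0.12, 0.01),
    labels: np.ndarray | None = None,
    source_indices: np.ndarray | None = None,
    record_every: int = 10,
) -> Projection:
    """Embed a dissimilarity matrix into 2D by the force scheme.

    Points start uniformly in the unit square (from ``seed``) and are
    refined for ``max_iter`` full sweeps with the learning rate decaying
    linearly between the two ``learning_rate`` bounds.  Deterministic for a
    given (delta, seed, max_iter, learning_rate).

    A monotone safeguard keeps the recorded stress non-increasing: whenever
    the stress after a checkpoint block of sweeps exceeds the previous
    checkpoint, the block is rolled back and re-run with a halved step
    scale (up to a few times).  This damps the oscillation large early
    steps can cause without changing the converged layout.
    """
    delta = validate_dissimilarity(delta)
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    n = delta.shape[0]
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, size=(n, 2))
    lr0, lr1 = learning_rate
    fracs = np.arange(max_iter) / (max_iter - 1) if max_iter > 1 else np.ones(1)
    lrs = lr0 + (lr1 - lr0) * fracs
    orders = np.stack([rng.permutation(n) for _ in range(max_iter)])
    history = []
    prev = stress(coords, delta)
    for start in range(0, max_iter, record_every):
        stop = min(start + record_every, max_iter)
        saved = coords.copy()
        scale = 1.0
        _sweeps(coords, delta, orders[start:stop], lrs[start:stop])
        s = stress(coords, delta)
        for _ in range(2):  # monotone safeguard: roll back and damp
            if s <= prev:
                break
            coords[:] = saved
            scale *= 0.5
            _sweeps(coords, delta, orders[start:stop], scale * lrs[start:stop])
            s = stress(coords, delta)
        if s > prev:
            coords[:] = saved
            s = prev
        history.append(s)
        prev = s
    return Projection(
        coords=coords,
        labels=labels,
        source_indices=source_indices,
        seed=seed,
        n_iterations=max_iter,
        stress_history=np.asarray(history),
    )


def replicate_projections(
    delta: np.ndarray,
    n_replicates: int,
    base_seed: int = 0,
    **kwargs,
) -> list[Projection]:
    """Independent projections with seeds ``base_seed, base_seed+1, ...``.

    The first replicate is identical to ``force_scheme(delta, base_seed)``.
    Used downstream for replicate means and standard deviations of the
    projection statistics (layout noise estimation).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return [
        force_scheme(delta, seed=int((base_seed + i) % 2**31), **kwargs)
        for i in range(n_replicates)
    ]
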