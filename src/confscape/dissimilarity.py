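"""Pairwise structural dissimilarity from the Q_w order parameter.

Q_w compares two conformations through all their internal Cα–Cα distances:

    Q_w(k, l) = (1/N_p) Σ_{i<j} exp[ -(r_ij^k - r_ij^l)^2 / (2 σ_ij^2) ]

with the sequence-separation weight σ_ij = |i - j|^0.15 (Å).  Q_w is 1 for
identical internal geometry and tends to 0 for very different structures;
the dissimilarity used throughout is δ(k, l) = 1 - Q_w(k, l), which lies in
[0, 1), is symmetric, and is invariant under rigid motion of either
conformation since only internal distances enter.

Adjacent (|i-j| = 1) pairs are included by default — their σ is 1 Å and at
fixed bond length they contribute exactly 1 to the sum — with an option to
exclude short-range pairs for sensitivity checks.
"""

from __future__ import annotations

import numpy as np

from .ensembles import PooledSet

__all__ = [
    "sigma",
    "pair_indices",
    "internal_distances",
    "qw_pair",
    "dissimilarity_matrix",
    "validate_dissimilarity",
    "MatrixSizeError",
]

SIGMA_EXPONENT = 0.15


class MatrixSizeError(MemoryError):
    """The requested dense dissimilarity matrix exceeds the memory cap."""


def sigma(i: int, j: int) -> float:
    """Sequence-separation weight σ_ij = |i - j|^0.15 in Å.

    Only the separation matters; ``i`` and ``j`` are 1-based sequence
    positions (or any consistent integer indexing).
    """
    sep = abs(int(i) - int(j))
    if sep == 0:
        raise ValueError("sigma is undefined for i == j")
    return float(sep) ** SIGMA_EXPONENT


def pair_indices(n_residues: int, exclude_adjacent: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle residue pairs (i < j), optionally without |i-j| = 1."""
    iu, ju = np.triu_indices(n_residues, k=2 if exclude_adjacent else 1)
    return iu, ju


def internal_distances(xyz: np.ndarray, exclude_adjacent: bool = False) -> np.ndarray:
    """All pairwise Cα distances per conformation.

    ``xyz`` may be one conformation (R, 3) or a stack (N, R, 3); returns
    (N_p,) or (N, N_p) with pairs ordered as :func:`pair_indices`.
    """
    xyz = np.asarray(xyz, dtype=np.float64)
    single = xyz.ndim == 2
    if single:
        xyz = xyz[None]
    iu, ju = pair_indices(xyz.shape[1], exclude_adjacent)
    d = np.linalg.norm(xyz[:, iu] - xyz[:, ju], axis=-1)
    return d[0] if single else d


def _pair_weights(n_residues: int, exclude_adjacent: bool) -> np.ndarray:
    """1 / (2 σ_ij²) per pair, matching :func:`pair_indices` ordering."""
    iu, ju = pair_indices(n_residues, exclude_adjacent)
    sep = (ju - iu).astype(np.float64)
    return 0.5 / sep ** (2 * SIGMA_EXPONENT)


def qw_pair(conf_k: np.ndarray, conf_l: np.ndarray, exclude_adjacent: bool = False) -> float:
    """Structural similarity Q_w between two conformations, in (0, 1]."""
    conf_k = np.asarray(conf_k, dtype=np.float64)
    conf_l = np.asarray(conf_l, dtype=np.float64)
    if conf_k.shape != conf_l.shape:
        raise ValueError(
            f"conformations must have identical shape, got {conf_k.shape} vs {conf_l.shape}"
        )
    dk = internal_distances(conf_k, exclude_adjacent)
    dl = internal_distances(conf_l, exclude_adjacent)
    w = _pair_weights(conf_k.shape[0], exclude_adjacent)
    return float(np.mean(np.exp(-((dk - dl) ** 2) * w)))


def dissimilarity_matrix(
    pooled: PooledSet | np.ndarray,
    exclude_adjacent: bool = False,
    max_gb: float = 6.0,
) -> np.ndarray:
    """Dense symmetric matrix δ(k, l) = 1 - Q_w(k, l) over all conformations.

    Refuses to allocate a matrix larger than ``max_gb`` GiB (dense float64);
    the cap is configurable because the matrix is the pipeline's dominant
    memory cost.
    """
    xyz = pooled.xyz if isinstance(pooled, PooledSet) else np.asarray(pooled, dtype=np.float64)
    if xyz.ndim != 3 or xyz.shape[0] == 0:
        raise ValueError("expected a non-empty (N, R, 3) conformation stack")
    n = xyz.shape[0]
    needed_gb = n * n * 8 / 1024**3
    if needed_gb > max_gb:
        raise MatrixSizeError(
            f"{n} conformations need a {needed_gb:.1f} GiB dense matrix, "
            f"above the {max_gb:.1f} GiB cap; raise max_gb or subsample"
        )
    d = internal_distances(xyz, exclude_adjacent)  # (N, N_p)
    w = _pair_weights(xyz.shape[1], exclude_adjacent)
    delta = np.zeros((n, n))
    for k in range(n - 1):
        diff = d[k + 1 :] - d[k]
        q = np.exp(-(diff * diff) * w).mean(axis=1)
        delta[k, k + 1 :] = 1.0 - q
        delta[k + 1 :, k] = delta[k, k + 1 :]
    np.clip(delta, 0.0, None, out=delta)
    np.fill_diagonal(delta, 0.0)
    return delta


def validate_dissimilarity(delta: np.ndarray) -> np.ndarray:
    """Check matrix invariants (square, symmetric, zero diagonal, [0, 1))."""
    delta = np.asarray(delta, dtype=np.float64)
    if delta.ndim != 2 or delta.shape[0] != delta.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.all(np.isfinite(delta)):
        raise ValueError("dissimilarity matrix contains non-finite entries")
    if np.any(np.diagonal(delta) != 0.0):
        raise ValueError("dissimilarity matrix must have an exactly zero diagonal")
    if not np.array_equal(delta, delta.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if delta.min() < 0.0 or delta.max() >= 1.0:
        raise ValueError("dissimilarity entries must lie in [0, 1)")
    return delta
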