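"""Cylindrical binding sectors around a fixed reference particle.

For a chain bound to a disc-shaped particle (the nucleosome-core analogue),
each frame is classified by the cylindrical coordinates of a tracked center
of mass relative to the particle frame: sector 0 collects unbound frames
(radial distance beyond a threshold), and the azimuth is divided into seven
equal wedges (sectors 1–7), with sector 1 centered on the dyad direction.

The particle frame is taken from the principal axes of the reference
coordinates: the axial direction is the smallest-extent axis (a disc's
symmetry axis) and the dyad direction is the largest-extent in-plane axis,
oriented toward the bead farthest from the center so the frame is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SectorGeometry",
    "SectorTrace",
    "GeometryError",
    "particle_frame",
    "cylindrical_coordinates",
    "assign_sectors",
    "sector_occupancy",
    "stratify_projection",
    "sector_azimuth_center",
    "sector_azimuth_halfwidth",
]

N_WEDGES = 7  # azimuthal sectors 1..7; sector 0 is reserved for unbound frames


class GeometryError(ValueError):
    """Invalid sector geometry (overlapping or non-covering wedges)."""


def sector_azimuth_halfwidth() -> float:
    return np.pi / N_WEDGES


def sector_azimuth_center(sector: int) -> float:
    """Azimuth (rad) of the wedge center for sectors 1..7; sector 1 at 0 (dyad)."""
    if not 1 <= sector <= N_WEDGES:
        raise ValueError(f"azimuthal sector must be 1..{N_WEDGES}, got {sector}")
    return float(np.angle(np.exp(1j * (sector - 1) * 2 * np.pi / N_WEDGES)))


@dataclass(frozen=True)
class SectorGeometry:
    """Geometry of the sector decomposition.

    ``boundaries`` optionally overrides the default equal wedges with
    explicit ``(lo, hi)`` azimuth intervals (radians, half-open ``[lo, hi)``)
    for sectors 1..7; they must partition the circle.
    """

    unbound_radius: float
    boundaries: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.unbound_radius <= 0:
            raise GeometryError("unbound_radius must be > 0")
        if self.boundaries is not None:
            b = tuple((float(lo), float(hi)) for lo, hi in self.boundaries)
            object.__setattr__(self, "boundaries", b)
            if len(b) != N_WEDGES:
                raise GeometryError(f"expected {N_WEDGES} azimuth intervals, got {len(b)}")
            widths = [(hi - lo) % (2 * np.pi) or 2 * np.pi for lo, hi in b]
            if not np.isclose(sum(widths), 2 * np.pi, atol=1e-9):
                raise GeometryError(
                    "azimuth intervals must cover the circle exactly once "
                    f"(total width {sum(widths):.6f} rad)"
                )

    def azimuthal_sector(self, theta: np.ndarray) -> np.ndarray:
        theta = np.angle(np.exp(1j * np.asarray(theta, dtype=float)))
        if self.boundaries is None:
            width = 2 * np.pi / N_WEDGES
            k = np.floor(((theta + width / 2) % (2 * np.pi)) / width).astype(np.int64)
            return k + 1
        out = np.full(theta.shape, -1, dtype=np.int64)
        for idx, (lo, hi) in enumerate(self.boundaries, start=1):
            span = (theta - lo) % (2 * np.pi)
            width = (hi - lo) % (2 * np.pi) or 2 * np.pi
            hit = span < width
            if np.any(out[hit] != -1):
                raise GeometryError("overlapping azimuth intervals")
            out[hit] = idx
        if np.any(out == -1):
            raise GeometryError("azimuth intervals do not cover the circle")
        return out


@dataclass
class SectorTrace:
    """Per-frame cylindrical coordinates and sector assignment."""

    r: np.ndarray  # radial distance in the disc plane (Å)
    theta: np.ndarray  # azimuth (rad), 0 at the dyad direction
    z: np.ndarray  # axial offset (Å)
    sector: np.ndarray  # id in {0..7}

    def __post_init__(self) -> None:
        n = len(self.r)
        for name in ("theta", "z", "sector"):
            if len(getattr(self, name)) != n:
                raise ValueError("trace arrays must have equal length")
        self.sector = np.asarray(self.sector, dtype=np.int64)
        if self.sector.size and (self.sector.min() < 0 or self.sector.max() > 7):
            raise ValueError("sector ids must lie in 0..7")

    @property
    def n_frames(self) -> int:
        return len(self.r)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("frame\tr\ttheta\tz\tsector\n")
            for f in range(self.n_frames):
                fh.write(
                    f"{f}\t{self.r[f]:.4f}\t{self.theta[f]:.6f}\t"
                    f"{self.z[f]:.4f}\t{self.sector[f]}\n"
                )


def particle_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal frame (origin, axes) of a reference particle.

    Returns the centroid and a (3, 3) array of rows (dyad, in-plane normal,
    axial).  Axial is the smallest-extent principal axis; the dyad axis is
    oriented toward the coordinate farthest from the centroid.
    """
    coords = np.asarray(coords, dtype=float)
    origin = coords.mean(axis=0)
    centered = coords - origin
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    axial = evecs[:, 0]
    dyad = evecs[:, 2]
    far = centered[np.argmax(np.linalg.norm(centered, axis=1))]
    if far @ dyad < 0:
        dyad = -dyad
    second = np.cross(axial, dyad)
    second /= np.linalg.norm(second)
    axial = np.cross(dyad, second)  # right-handed, exactly orthonormal
    return origin, np.stack([dyad, second, axial])


def cylindrical_coordinates(
    points: np.ndarray, origin: np.ndarray, axes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(r, theta, z) of points in the particle frame; theta=0 on the dyad axis."""
    rel = np.atleast_2d(points) - origin
    x = rel @ axes[0]
    y = rel @ axes[1]
    z = rel @ axes[2]
    return np.hypot(x, y), np.arctan2(y, x), z


def assign_sectors(
    com_points: np.ndarray,
    reference_coords: np.ndarray,
    geometry: SectorGeometry,
) -> SectorTrace:
    """Map each tracked center-of-mass point to exactly one sector.

    Sector 0 iff the in-plane radial distance exceeds ``unbound_radius``;
    otherwise the azimuthal wedge (1..7) containing the point.
    """
    origin, axes = particle_frame(reference_coords)
    r, theta, z = cylindrical_coordinates(com_points, origin, axes)
    sector = np.where(r > geometry.unbound_radius, 0, geometry.azimuthal_sector(theta))
    return SectorTrace(r=r, theta=theta, z=z, sector=sector)


def center_of_mass(xyz: np.ndarray, atom_slice: slice | np.ndarray) -> np.ndarray:
    """Uniform-mass center of the selected beads, per frame: (F, 3)."""
    return np.asarray(xyz, dtype=float)[:, atom_slice].mean(axis=1)


def sector_occupancy(trace: SectorTrace) -> np.ndarray:
    """Occupancy percentage per sector id 0..7 (sums to 100)."""
    if trace.n_frames == 0:
        raise ValueError("empty trace")
    counts = np.bincount(trace.sector, minlength=8)[:8]
    return 100.0 * counts / trace.n_frames


def stratify_projection(coords: np.ndarray, trace: SectorTrace) -> dict[int, np.ndarray]:
    """Per-sector index arrays into the projection, for overlays and per-sector stats.

    ``coords`` is the (N, 2) projected point set in frame order; it must have
    one point per trace frame.
    """
    coords = np.asarray(coords)
    if coords.shape[0] != trace.n_frames:
        raise ValueError(
            f"projection has {coords.shape[0]} points but trace has {trace.n_frames} frames"
        )
    return {
        s: np.flatnonzero(trace.sector == s)
        for s in range(8)
        if np.any(trace.sector == s)
    }
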