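"""Synthetic Cα ensembles with controllable landscape structure.

Real disordered-tail trajectories are not redistributable, so the analysis
is exercised on synthetic polymer ensembles that reproduce the statistical
structure it assumes: several labeled models sharing one conformational
space but differing in compactness (hence Rg distribution), optionally with
an engineered exclusive conformational mode (pair contacts forced within a
cutoff, e.g. a hairpin), and a three-domain chain whose middle-domain
center of mass moves among cylindrical sectors around a fixed reference
particle.

The generator is a self-avoiding-biased random walk: each bead is placed at
fixed bond length from the previous one, with the step direction biased
toward the centroid of the beads already placed.  The bias strength maps
linearly from the ``compactness`` parameter, which gives a monotone,
easily calibrated handle on the Rg distribution without pretending to any
force-field physics.  Exclusive motifs are enforced exactly by guided
growth plus rejection sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensembles import ConformationEnsemble
from .sectors import (
    SectorGeometry,
    SectorTrace,
    cylindrical_coordinates,
    particle_frame,
    sector_azimuth_center,
    sector_azimuth_halfwidth,
)

__all__ = [
    "PolymerSpec",
    "SectorSystemSpec",
    "MotifError",
    "generate_polymer_ensemble",
    "generate_sector_system",
    "EXCLUDED_VOLUME_CUTOFF",
]

# Nonbonded beads closer than this are rejected during growth; prevents the
# degenerate overlaps that would make Q_w trivially high.
EXCLUDED_VOLUME_CUTOFF = 2.0  # Å

_MOTIF_RETRY_CAP = 10_000  # rejection-sampling attempts per frame
_COMPACTNESS_GAIN = 1.0  # centroid-bias strength at compactness = 1


class MotifError(ValueError):
    """An exclusive-motif constraint cannot be satisfied."""


@dataclass(frozen=True)
class PolymerSpec:
    """Specification of one synthetic polymer model.

    Parameters
    ----------
    n_residues : int
        Chain length (>= 4).
    bond_length : float
        Successive Cα–Cα distance in Å (default 3.8, the trans-peptide value).
    compactness : float in [0, 1]
        Collapse bias; 0 is a freely jointed chain, larger values give
        stochastically smaller mean Rg.
    compactness_spread : float
        Half-width of a per-frame uniform jitter on ``compactness`` (clipped
        to [0, 1]); nonzero values emulate a heterogeneous ensemble mixing
        extended and collapsed sub-populations.
    exclusive_motif : list of (i, j, cutoff) or None
        0-based residue pairs forced within ``cutoff`` Å in every frame.
    seed : int
        Seed for the generator's random stream.
    """

    n_residues: int
    bond_length: float = 3.8
    compactness: float = 0.0
    compactness_spread: float = 0.0
    exclusive_motif: tuple[tuple[int, int, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("n_residues must be >= 4")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be > 0")
        if not 0.0 <= self.compactness <= 1.0:
            raise ValueError("compactness must lie in [0, 1]")
        if self.compactness_spread < 0.0:
            raise ValueError("compactness_spread must be >= 0")
        if self.exclusive_motif is not None:
            motif = tuple(
                (min(int(i), int(j)), max(int(i), int(j)), float(cut))
                for i, j, cut in self.exclusive_motif
            )
            object.__setattr__(self, "exclusive_motif", motif)
            for i, j, cut in motif:
                if not (0 <= i < j < self.n_residues):
                    raise MotifError(f"motif pair ({i}, {j}) out of range for {self.n_residues} residues")
                floor = self.bond_length if j - i == 1 else EXCLUDED_VOLUME_CUTOFF
                if cut < floor:
                    raise MotifError(
                        f"motif pair ({i}, {j}) unsatisfiable: cutoff {cut} Å is below "
                        f"the minimum achievable separation {floor} Å"
                    )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / np.where(n < 1e-12, 1.0, n)


def _random_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    return _unit(rng.standard_normal((n, 3)))


def _grow_chains(
    rng: np.random.Generator,
    n_frames: int,
    n_residues: int,
    bond: float,
    kappa: np.ndarray,
    motifs: tuple[tuple[int, int, float], ...],
) -> np.ndarray:
    """Grow ``n_frames`` chains simultaneously, one bead per outer step.

    ``kappa`` has shape (n_frames, n_residues): the centroid-bias strength
    per frame and bead.  Excluded volume is enforced by resampling the step
    direction for offending frames.
    """
    pos = np.zeros((n_frames, n_residues, 3))
    pos[:, 1] = bond * _random_unit(rng, n_frames)
    for m in range(2, n_residues):
        pending = np.arange(n_frames)
        retries = 0
        while pending.size:
            prev = pos[pending, m - 1]
            d = _random_unit(rng, pending.size)
            km = kappa[pending, m]
            if np.any(km > 0):
                centroid = pos[pending, :m].mean(axis=1)
                d = d + km[:, None] * _unit(centroid - prev)
            for i, j, cut in motifs:
                if i < m <= j:
                    vec = pos[pending, i] - prev
                    dist = np.linalg.norm(vec, axis=-1)
                    bonds_left = j - (m - 1)
                    # slack < 0 means the target is comfortably reachable;
                    # the pull ramps up as the reachable budget is consumed.
                    # The wide ramp keeps guided contacts tight (well inside
                    # the cutoff), which is what makes an engineered motif a
                    # well-defined conformational mode.
                    slack = dist - (cut + (bonds_left - 1) * bond)
                    w = 3.0 * np.clip(1.0 + slack / (3.0 * bond), 0.0, 1.0)
                    d = d + w[:, None] * _unit(vec)
            cand = prev + bond * _unit(d)
            if m >= 2:
                older = pos[pending, : m - 1]  # all beads except the bonded neighbour
                dmin = np.linalg.norm(older - cand[:, None, :], axis=-1).min(axis=1)
                ok = dmin >= EXCLUDED_VOLUME_CUTOFF
            else:
                ok = np.ones(pending.size, dtype=bool)
            pos[pending[ok], m] = cand[ok]
            pending = pending[~ok]
            if pending.size:
                retries += 1
                if retries > 500:  # geometrically trapped; accept the overlap
                    pos[pending, m] = cand[~ok]
                    break
    return pos


def _project_bonds(xyz: np.ndarray, bond: float) -> None:
    """Restore exact bond lengths in place by sequential projection."""
    for m in range(1, xyz.shape[1]):
        v = xyz[:, m] - xyz[:, m - 1]
        xyz[:, m] = xyz[:, m - 1] + bond * _unit(v)


def _repair_frames(
    xyz: np.ndarray, motifs, bond: float, n_iter: int = 80
) -> np.ndarray:
    """Relax frames onto the motif constraints (in place); returns a success mask.

    Alternates three vectorized moves: pull each open contact pair toward a
    point just inside its cutoff, push apart nonbonded beads overlapping the
    excluded volume, and re-project all bonds to their exact length.  This is
    a constraint-relaxation pass, not a physical dynamics; it converges in a
    few dozen iterations for loop/hairpin motifs at these cutoffs.
    """
    n_res = xyz.shape[1]
    iu, ju = np.triu_indices(n_res, k=2)  # nonbonded pairs for excluded volume

    def unresolved(sub: np.ndarray) -> np.ndarray:
        bad = _motif_violations(sub, motifs)
        d = np.linalg.norm(sub[:, iu] - sub[:, ju], axis=-1)
        return bad | (d < EXCLUDED_VOLUME_CUTOFF).any(axis=1)

    active = np.flatnonzero(unresolved(xyz))
    for _ in range(n_iter):
        if active.size == 0:
            break
        sub = xyz[active]
        for i, j, cut in motifs:
            v = sub[:, j] - sub[:, i]
            dist = np.linalg.norm(v, axis=-1)
            target = 0.9 * cut
            over = dist > target
            if over.any():
                shift = (0.5 * (dist[over] - target) / dist[over])[:, None] * v[over]
                sub[over, i] += shift
                sub[over, j] -= shift
        d = np.linalg.norm(sub[:, iu] - sub[:, ju], axis=-1)
        clash = d < EXCLUDED_VOLUME_CUTOFF
        if clash.any():
            f, p = np.nonzero(clash)
            v = sub[f, ju[p]] - sub[f, iu[p]]
            dist = np.maximum(d[f, p], 1e-6)
            shift = (0.5 * (EXCLUDED_VOLUME_CUTOFF * 1.05 - dist) / dist)[:, None] * v
            np.subtract.at(sub, (f, iu[p]), shift)
            np.add.at(sub, (f, ju[p]), shift)
        _project_bonds(sub, bond)
        xyz[active] = sub
        active = active[unresolved(sub)]
    return ~unresolved(xyz)


def _motif_violations(xyz: np.ndarray, motifs) -> np.ndarray:
    """Boolean mask of frames violating any motif constraint."""
    bad = np.zeros(xyz.shape[0], dtype=bool)
    for i, j, cut in motifs:
        d = np.linalg.norm(xyz[:, i] - xyz[:, j], axis=-1)
        bad |= d > cut
    return bad


def generate_polymer_ensemble(
    spec: PolymerSpec, n_frames: int, label: str | None = None
) -> ConformationEnsemble:
    """Generate ``n_frames`` conformations of the chain described by ``spec``.

    Deterministic for a given (spec, n_frames).  Every frame satisfies all
    exclusive-motif constraints exactly (rejection sampling with a retry cap
    of 10,000 per frame).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)

    def frame_kappa(k: int) -> np.ndarray:
        c = np.full(k, spec.compactness)
        if spec.compactness_spread > 0:
            c = np.clip(c + rng.uniform(-spec.compactness_spread, spec.compactness_spread, k), 0.0, 1.0)
        return np.repeat((_COMPACTNESS_GAIN * c)[:, None], spec.n_residues, axis=1)

    motifs = spec.exclusive_motif or ()
    xyz = _grow_chains(rng, n_frames, spec.n_residues, spec.bond_length, frame_kappa(n_frames), motifs)

    iu, ju = np.triu_indices(spec.n_residues, k=2)

    def failing(indices: np.ndarray) -> np.ndarray:
        sub = xyz[indices]
        bad = _motif_violations(sub, motifs) if motifs else np.zeros(len(sub), bool)
        d = np.linalg.norm(sub[:, iu] - sub[:, ju], axis=-1)
        return indices[bad | (d < EXCLUDED_VOLUME_CUTOFF).any(axis=1)]

    def repair(indices: np.ndarray) -> np.ndarray:
        if indices.size == 0:
            return indices
        sub = xyz[indices]
        ok = _repair_frames(sub, motifs, spec.bond_length)
        xyz[indices] = sub
        return indices[~ok]

    bad = repair(failing(np.arange(n_frames)))
    attempts = np.ones(n_frames, dtype=np.int64)
    while bad.size:
        attempts[bad] += 1
        if (attempts[bad] > _MOTIF_RETRY_CAP).any():
            for i, j, cut in motifs:
                d = np.linalg.norm(xyz[bad, i] - xyz[bad, j], axis=-1)
                if (d > cut).any():
                    raise MotifError(
                        f"motif pair ({i}, {j}) within {cut} Å not satisfied "
                        f"after {_MOTIF_RETRY_CAP} attempts per frame"
                    )
            raise RuntimeError("excluded-volume constraint unsatisfiable")  # pragma: no cover
        xyz[bad] = _grow_chains(
            rng, bad.size, spec.n_residues, spec.bond_length, frame_kappa(bad.size), motifs
        )
        bad = repair(failing(bad))
    return ConformationEnsemble(label=label or f"polymer_seed{spec.seed}", xyz=xyz)


def tail_study_specs(seed: int = 1, n_residues: int = 26) -> dict[str, PolymerSpec]:
    """The six-model synthetic study conditions for the landscape comparison.

    Emulates a wild-type disordered tail compared against five modified
    variants.  The premise: each modification stabilizes a specific set of
    transient intramolecular contacts, narrowing the accessible ensemble,
    while the wild type samples the shared conformational space freely.

    * ``WT`` — unconstrained chain, the broadest ensemble.
    * ``A1a`` — a fully zipped hairpin (six nested contacts closed within
      6 Å): a tight exclusive conformational mode, the narrowest ensemble.
    * ``A1b``/``A2`` — single stabilized loops in the N- and C-terminal
      halves respectively (two contacts each).
    * ``A3`` — both terminal halves looped (three contacts).
    * ``A4`` — two separate internal loops (two contacts).

    All models share chain length, bond length and collapse bias, so the
    differences the analysis detects come from the engineered contact
    structure, not from trivial size effects.
    """
    c = 0.5
    return {
        "WT": PolymerSpec(n_residues, compactness=c, seed=seed),
        "A1a": PolymerSpec(
            n_residues,
            compactness=0.45,
            exclusive_motif=tuple((i, n_residues - 1 - i, 6.0) for i in (1, 3, 5, 7, 9, 11)),
            seed=seed + 1,
        ),
        "A1b": PolymerSpec(
            n_residues, compactness=c, exclusive_motif=((2, 15, 6.5), (5, 12, 6.5)), seed=seed + 2
        ),
        "A2": PolymerSpec(
            n_residues, compactness=c, exclusive_motif=((10, 23, 6.5), (13, 20, 6.5)), seed=seed + 3
        ),
        "A3": PolymerSpec(
            n_residues,
            compactness=c,
            exclusive_motif=((0, 11, 6.5), (14, 25, 6.5), (3, 8, 6.5)),
            seed=seed + 4,
        ),
        "A4": PolymerSpec(
            n_residues, compactness=c, exclusive_motif=((3, 10, 6.0), (16, 23, 6.0)), seed=seed + 5
        ),
    }


def generate_mixture_ensemble(
    specs: list[PolymerSpec],
    n_frames: int,
    label: str,
    proportions: list[float] | None = None,
) -> ConformationEnsemble:
    """One labeled ensemble drawn from several conformational sub-populations.

    Emulates a multi-basin ensemble: ``n_frames`` are split among the given
    specs (equally, or by ``proportions``) and concatenated under a single
    label.  All specs must share chain length and bond length.  Deterministic
    via each spec's own seed.
    """
    if not specs:
        raise ValueError("need at least one sub-population spec")
    if len({(s.n_residues, s.bond_length) for s in specs}) != 1:
        raise ValueError("all sub-populations must share n_residues and bond_length")
    if proportions is None:
        proportions = [1.0 / len(specs)] * len(specs)
    if len(proportions) != len(specs) or min(proportions) <= 0:
        raise ValueError("proportions must be positive, one per spec")
    w = np.asarray(proportions, dtype=float)
    w /= w.sum()
    counts = np.floor(w * n_frames).astype(int)
    counts[0] += n_frames - counts.sum()  # remainder to the first component
    parts = [
        generate_polymer_ensemble(s, int(k)).xyz for s, k in zip(specs, counts) if k > 0
    ]
    return ConformationEnsemble(label=label, xyz=np.concatenate(parts, axis=0))


# ---------------------------------------------------------------------------
# Three-domain chain bound to a reference particle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SectorSystemSpec:
    """A three-domain chain (N-tail, globular, C-tail) near a disc particle.

    ``sector_schedule`` lists (sector id, n_frames) blocks; the generated
    frames place the globular-domain center of mass inside the scheduled
    cylindrical sector of the reference particle, well away from sector
    boundaries, and the true sector labels are returned for recovery tests.
    """

    n_nter: int
    n_globular: int
    n_cter: int
    sector_schedule: tuple[tuple[int, int], ...]
    reference_radius: float = 40.0
    bond_length: float = 3.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n in (("n_nter", self.n_nter), ("n_globular", self.n_globular), ("n_cter", self.n_cter)):
            if n < 1:
                raise ValueError(f"{name} must be >= 1 (got {n})")
        schedule = tuple((int(s), int(k)) for s, k in self.sector_schedule)
        object.__setattr__(self, "sector_schedule", schedule)
        if not schedule:
            raise ValueError("sector_schedule must be non-empty")
        for s, k in schedule:
            if not 0 <= s <= 7:
                raise ValueError(f"sector id {s} outside 0..7")
            if k < 1:
                raise ValueError("each schedule entry needs n_frames >= 1")
        if self.reference_radius <= 0:
            raise ValueError("reference_radius must be > 0")

    @property
    def n_residues(self) -> int:
        return self.n_nter + self.n_globular + self.n_cter

    @property
    def globular_slice(self) -> slice:
        return slice(self.n_nter, self.n_nter + self.n_globular)

    def reference_particle(self) -> np.ndarray:
        """Fixed disc-shaped reference particle with a dyad marker bead.

        Two concentric rings in the disc plane plus a marker bead beyond the
        rim mark the in-plane dyad direction, so the principal-axes frame
        recovered from these coordinates is unambiguous.
        """
        r = self.reference_radius
        ang = np.linspace(0.0, 2 * np.pi, 24, endpoint=False)
        outer = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros_like(ang)], axis=1)
        inner = np.stack(
            [0.55 * r * np.cos(ang), 0.55 * r * np.sin(ang), np.zeros_like(ang)], axis=1
        )
        marker = np.array([[1.35 * r, 0.0, 0.0]])
        caps = np.array([[0.0, 0.0, 0.12 * r], [0.0, 0.0, -0.12 * r]])
        return np.concatenate([outer, inner, marker, caps], axis=0)

    def default_geometry(self) -> SectorGeometry:
        return SectorGeometry(unbound_radius=self.reference_radius + 20.0)


def generate_sector_system(
    spec: SectorSystemSpec,
) -> tuple[ConformationEnsemble, SectorTrace]:
    """Generate chain frames following the sector schedule, with ground truth.

    Each frame is a bonded three-domain walk (flexible tails, compact middle
    domain) rigidly translated so the globular-domain center of mass sits at
    a point drawn inside the scheduled sector (80% of the wedge width, radii
    within [0.35, 0.9] of the unbound threshold for bound sectors; 1.2–1.8
    of it for unbound frames).
    """
    rng = np.random.default_rng(spec.seed)
    geometry = spec.default_geometry()
    particle = spec.reference_particle()
    origin, axes = particle_frame(particle)

    n_total = sum(k for _, k in spec.sector_schedule)
    n_res = spec.n_residues
    profile = np.full(n_res, 0.2)
    profile[spec.globular_slice] = 1.0  # compact middle domain, flexible tails
    kappa = np.repeat(profile[None, :], n_total, axis=0)
    xyz = _grow_chains(rng, n_total, n_res, spec.bond_length, kappa, ())

    sectors = np.empty(n_total, dtype=np.int64)
    r_t = np.empty(n_total)
    theta_t = np.empty(n_total)
    z_t = np.empty(n_total)
    start = 0
    half = sector_azimuth_halfwidth()
    for sector, k in spec.sector_schedule:
        sl = slice(start, start + k)
        sectors[sl] = sector
        if sector == 0:
            r_t[sl] = geometry.unbound_radius * rng.uniform(1.2, 1.8, k)
            theta_t[sl] = rng.uniform(-np.pi, np.pi, k)
        else:
            r_t[sl] = geometry.unbound_radius * rng.uniform(0.35, 0.9, k)
            theta_t[sl] = sector_azimuth_center(sector) + rng.uniform(-0.8, 0.8, k) * half
        z_t[sl] = rng.uniform(-5.0, 5.0, k)
        start += k

    targets = (
        origin[None, :]
        + r_t[:, None] * (np.cos(theta_t)[:, None] * axes[0] + np.sin(theta_t)[:, None] * axes[1])
        + z_t[:, None] * axes[2]
    )
    com = xyz[:, spec.globular_slice].mean(axis=1)
    xyz += (targets - com)[:, None, :]

    # wrap azimuths into (-pi, pi] for the trace
    theta_t = np.angle(np.exp(1j * theta_t))
    ensemble = ConformationEnsemble(label="sector_system", xyz=xyz)
    trace = SectorTrace(r=r_t, theta=theta_t, z=z_t, sector=sectors)
    return ensemble, trace


def write_sector_labels(trace: SectorTrace, path) -> None:
    """Write ground-truth sector labels as two-column text (frame, sector)."""
    with open(path, "w") as fh:
        fh.write("frame\tsector\n")
        for f, s in enumerate(trace.sector):
            fh.write(f"{f}\t{s}\n")
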