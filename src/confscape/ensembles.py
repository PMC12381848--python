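"""Labeled Cα conformational ensembles: containers, trajectory I/O, subsampling, pooling.

An ensemble is a labeled stack of frames, each an ordered list of Cα
positions in Å.  All downstream statistics operate on internal Cα–Cα
distances, so no superposition or alignment is ever applied; trajectories
are read as-is and only the Cα coordinates are retained.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConformationEnsemble",
    "PooledSet",
    "EnsembleError",
    "load_calpha_trajectory",
    "subsample",
    "pool",
    "write_pdb",
    "write_dcd",
    "write_xtc",
    "write_coordinate_table",
]


class EnsembleError(ValueError):
    """Raised for malformed or inconsistent ensemble inputs."""


@dataclass
class ConformationEnsemble:
    """A labeled set of Cα conformations.

    Parameters
    ----------
    label : str
        Model/system name (e.g. ``"WT"``, ``"A1a"``).
    xyz : ndarray, shape (n_frames, n_residues, 3)
        Cα coordinates in Å, ordered by residue index within each frame.
    source_indices : ndarray, shape (n_frames,), optional
        Original frame numbers in the source trajectory; defaults to
        ``0..n_frames-1``.  Must be strictly increasing.
    """

    label: str
    xyz: np.ndarray
    source_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise EnsembleError(
                f"xyz must have shape (n_frames, n_residues, 3), got {self.xyz.shape}"
            )
        if self.source_indices is None:
            self.source_indices = np.arange(self.n_frames, dtype=np.int64)
        else:
            self.source_indices = np.asarray(self.source_indices, dtype=np.int64)
            if self.source_indices.shape != (self.n_frames,):
                raise EnsembleError("source_indices must have one entry per frame")
            if self.n_frames > 1 and not np.all(np.diff(self.source_indices) > 0):
                raise EnsembleError("source_indices must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_residues(self) -> int:
        return self.xyz.shape[1]

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class PooledSet:
    """Conformations from several labeled ensembles pooled into one set.

    All compared models share a single conformational space: the pooled
    set concatenates their frames (order preserved within each model) and
    remembers which block belongs to which label.
    """

    xyz: np.ndarray  # (N, n_residues, 3) Å
    labels: np.ndarray  # (N,) str
    source_indices: np.ndarray  # (N,) original frame numbers
    offsets: dict[str, slice] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.n_conformations:
            raise EnsembleError("one label per conformation required")
        total = sum(s.stop - s.start for s in self.offsets.values())
        if self.offsets and total != self.n_conformations:
            raise EnsembleError("offsets do not cover the pooled set exactly")

    @property
    def n_conformations(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_residues(self) -> int:
        return self.xyz.shape[1]

    @property
    def model_labels(self) -> list[str]:
        return list(self.offsets.keys())

    def __len__(self) -> int:
        return self.n_conformations

    def indices_of(self, label: str) -> np.ndarray:
        if label not in self.offsets:
            raise KeyError(f"unknown model label {label!r}")
        s = self.offsets[label]
        return np.arange(s.start, s.stop)

    def write_manifest(self, path: str | os.PathLike) -> None:
        """Write (global index, label, source frame) as tab-separated text."""
        with open(path, "w") as fh:
            fh.write("index\tlabel\tsource_frame\n")
            for i, (lab, src) in enumerate(zip(self.labels, self.source_indices)):
                fh.write(f"{i}\t{lab}\t{src}\n")


def _scan_multimodel_pdb_counts(path: str | os.PathLike) -> list[int]:
    """Count Cα atoms per MODEL in a multi-model PDB (cheap text scan)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                name = line[12:16].strip()
                if name == "CA":
                    if not saw_model:  # single implicit model
                        in_model = True
                    current += 1
    if not saw_model:
        counts.append(current)
    elif in_model:  # MODEL without ENDMDL
        counts.append(current)
    return counts


def load_calpha_trajectory(
    path: str | os.PathLike, topology: str | os.PathLike | None = None
) -> ConformationEnsemble:
    """Read a trajectory and keep only Cα (or sole-bead) coordinates, in Å.

    Supports multi-model PDB (self-describing) and DCD/XTC with a PDB
    topology.  Coordinates are ordered by residue sequence position.

    Raises
    ------
    EnsembleError
        If frames have inconsistent residue counts (the first offending
        frame is named) or no Cα atoms are present.
    """
    import mdtraj as md

    path = os.fspath(path)
    if path.endswith(".pdb"):
        counts = _scan_multimodel_pdb_counts(path)
        if not counts or all(c == 0 for c in counts):
            raise EnsembleError(f"no CA atoms found in {path}")
        ref = counts[0]
        for frame, c in enumerate(counts):
            if c != ref:
                raise EnsembleError(
                    f"inconsistent residue count in frame {frame}: "
                    f"{c} CA atoms vs {ref} in frame 0"
                )
        traj = md.load(path)
    else:
        if topology is None:
            raise EnsembleError(f"{path}: a topology file is required for this format")
        traj = md.load(path, top=os.fspath(topology))

    ca = traj.topology.select("name CA")
    if ca.size == 0:
        # coarse-grained single-bead chains: accept one arbitrary bead per residue
        if traj.topology.n_atoms == traj.topology.n_residues:
            ca = np.arange(traj.topology.n_atoms)
        else:
            raise EnsembleError(f"no CA atoms found in {path}")
    order = np.argsort([traj.topology.atom(int(a)).residue.resSeq for a in ca], kind="stable")
    ca = ca[order]
    xyz = traj.xyz[:, ca, :].astype(np.float64) * 10.0  # nm -> Å
    label = os.path.splitext(os.path.basename(path))[0]
    return ConformationEnsemble(label=label, xyz=xyz)


def subsample(ensemble: ConformationEnsemble, discard: int, stride: int) -> ConformationEnsemble:
    """Retain frames ``discard, discard+stride, discard+2*stride, ...``.

    The first retained frame is the frame at 0-based index ``discard``
    (half-open ``[discard, end)`` with step ``stride``), i.e. discarding a
    burn-in of ``discard`` frames and then taking every ``stride``-th one.
    """
    if discard < 0:
        raise EnsembleError("discard must be >= 0")
    if stride < 1:
        raise EnsembleError("stride must be >= 1")
    if discard >= ensemble.n_frames:
        raise EnsembleError(
            f"discard={discard} leaves an empty ensemble "
            f"({ensemble.n_frames} frames available)"
        )
    idx = np.arange(discard, ensemble.n_frames, stride)
    return ConformationEnsemble(
        label=ensemble.label,
        xyz=ensemble.xyz[idx],
        source_indices=ensemble.source_indices[idx],
    )


def pool(ensembles: list[ConformationEnsemble]) -> PooledSet:
    """Concatenate labeled ensembles into one pooled conformation set."""
    if not ensembles:
        raise EnsembleError("cannot pool an empty list of ensembles")
    n_res = ensembles[0].n_residues
    for e in ensembles[1:]:
        if e.n_residues != n_res:
            raise EnsembleError(
                f"residue count mismatch: {ensembles[0].label!r} has {n_res}, "
                f"{e.label!r} has {e.n_residues}"
            )
    labels = [e.label for e in ensembles]
    if len(set(labels)) != len(labels):
        raise EnsembleError("model labels must be unique")
    offsets: dict[str, slice] = {}
    start = 0
    for e in ensembles:
        offsets[e.label] = slice(start, start + e.n_frames)
        start += e.n_frames
    return PooledSet(
        xyz=np.concatenate([e.xyz for e in ensembles], axis=0),
        labels=np.concatenate([np.repeat(e.label, e.n_frames) for e in ensembles]),
        source_indices=np.concatenate([e.source_indices for e in ensembles]),
        offsets=offsets,
    )


def _to_mdtraj(xyz_angstrom: np.ndarray):
    """Build an mdtraj Trajectory of single-Cα residues from (F, R, 3) Å."""
    import mdtraj as md

    n_res = xyz_angstrom.shape[1]
    top = md.Topology()
    chain = top.add_chain()
    carbon = md.element.carbon
    prev = None
    for i in range(n_res):
        res = top.add_residue("GLY", chain, resSeq=i + 1)
        atom = top.add_atom("CA", carbon, res)
        if prev is not None:
            top.add_bond(prev, atom)
        prev = atom
    return md.Trajectory(xyz=np.asarray(xyz_angstrom, dtype=np.float32) / 10.0, topology=top)


def write_pdb(ensemble: ConformationEnsemble, path: str | os.PathLike) -> None:
    """Write as Cα-only multi-model PDB, one MODEL per frame."""
    _to_mdtraj(ensemble.xyz).save_pdb(os.fspath(path))


def write_dcd(ensemble: ConformationEnsemble, path: str | os.PathLike) -> None:
    _to_mdtraj(ensemble.xyz).save_dcd(os.fspath(path))


def write_xtc(ensemble: ConformationEnsemble, path: str | os.PathLike) -> None:
    _to_mdtraj(ensemble.xyz).save_xtc(os.fspath(path))


def write_coordinate_table(ensemble: ConformationEnsemble, path: str | os.PathLike) -> None:
    """Write (frame, residue, x, y, z) as tab-separated text."""
    with open(path, "w") as fh:
        fh.write("frame\tresidue\tx\ty\tz\n")
        for f in range(ensemble.n_frames):
            src = ensemble.source_indices[f]
            for r in range(ensemble.n_residues):
                x, y, z = ensemble.xyz[f, r]
                fh.write(f"{src}\t{r}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")
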