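"""End-to-end analysis pipeline with a serializable run configuration.

Stages: load or generate labeled ensembles -> burn-in/stride subsampling ->
pooling -> Q_w dissimilarity matrix -> force-scheme projection(s) -> grid
statistics (fraction maps, overlap table with bootstrap errors, entropy
across replicates) -> local conformational signatures -> optional binding
sectors -> figures.  Every deterministic artifact is a pure function of
(config, seeds); a manifest records versions, seeds and input digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dissimilarity import dissimilarity_matrix
from .ensembles import (
    ConformationEnsemble,
    load_calpha_trajectory,
    pool,
    subsample,
    write_pdb,
)
from .landscape import (
    bin_projection,
    entropy_across_replicates,
    kde_density,
    overlap_uncertainty,
    relative_fraction_map,
)
from .lcs import RegionSelection, extract_lcs
from .metrics import radius_of_gyration, smoothness_score, write_observable_track
from .projection import replicate_projections
from .sectors import SectorGeometry, assign_sectors, center_of_mass, sector_occupancy, stratify_projection
from .synthetic import PolymerSpec, SectorSystemSpec, generate_polymer_ensemble, generate_sector_system

__all__ = ["RunConfig", "ModelConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("confscape")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class ModelConfig:
    """One labeled input: either a trajectory path or a synthetic spec."""

    label: str
    path: str | None = None
    topology: str | None = None
    synthetic: dict | None = None
    n_frames: int = 500

    def __post_init__(self) -> None:
        if (self.path is None) == (self.synthetic is None):
            raise ValueError(
                f"model {self.label!r}: specify exactly one of 'path' or 'synthetic'"
            )


@dataclass
class RunConfig:
    """Fully serializable description of one analysis run."""

    models: list[ModelConfig]
    output_dir: str = "results/run"
    seed: int = 0
    discard: int = 0
    stride: int = 1
    exclude_adjacent: bool = False
    max_matrix_gb: float = 6.0
    max_iter: int = 100
    lr_start: float = 0.12
    lr_end: float = 0.01
    n_replicates: int = 10
    grid: tuple[int, int] = (27, 27)
    min_count: int = 3
    lcs_n_neighbors: int = 30
    lcs_contact_cutoff: float = 8.0
    lcs_regions: list[dict] = field(default_factory=list)
    n_boot: int = 50
    sector_system: dict | None = None
    figures: bool = True

    def __post_init__(self) -> None:
        self.models = [
            m if isinstance(m, ModelConfig) else ModelConfig(**m) for m in self.models
        ]
        self.grid = tuple(self.grid)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._as_dict(), fh, sort_keys=False)

    def _as_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = list(self.grid)
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.1f s", name, time.time() - t0)
            return out

        return wrapped

    return deco


@_stage("inputs")
def _load_models(config: RunConfig) -> list[ConformationEnsemble]:
    ensembles = []
    for m in config.models:
        if m.synthetic is not None:
            spec = PolymerSpec(**m.synthetic)
            e = generate_polymer_ensemble(spec, m.n_frames, label=m.label)
        else:
            p = Path(m.path)
            if not p.exists():
                raise FileNotFoundError(f"model {m.label!r}: missing input {m.path}")
            e = load_calpha_trajectory(p, m.topology)
            e.label = m.label
        ensembles.append(e)
    return ensembles


def _digest(xyz: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(xyz).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the full analysis; returns a mapping of artifact name -> path."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    ensembles = _load_models(config)

    @_stage("subsample+pool")
    def _pool():
        subs = [subsample(e, config.discard, config.stride) for e in ensembles]
        return pool(subs)

    pooled = _pool()
    pooled.write_manifest(out / "pooled_manifest.tsv")
    save("pooled_manifest", out / "pooled_manifest.tsv")

    @_stage("dissimilarity")
    def _delta():
        d = dissimilarity_matrix(
            pooled, exclude_adjacent=config.exclude_adjacent, max_gb=config.max_matrix_gb
        )
        log.info("dissimilarity matrix: %d x %d", *d.shape)
        return d

    delta = _delta()
    np.save(out / "dissimilarity.npy", delta)
    save("dissimilarity", out / "dissimilarity.npy")

    @_stage("projection")
    def _project():
        return replicate_projections(
            delta,
            config.n_replicates,
            base_seed=config.seed,
            max_iter=config.max_iter,
            learning_rate=(config.lr_start, config.lr_end),
            labels=pooled.labels,
            source_indices=pooled.source_indices,
        )

    projections = _project()
    proj = projections[0]
    for i, p in enumerate(projections):
        p.write(out / f"projection_{i:02d}.tsv")
    save("projection", out / "projection_00.tsv")

    @_stage("landscape-stats")
    def _stats():
        occ = bin_projection(proj, config.grid, config.min_count)
        for lab in occ.labels:
            F = relative_fraction_map(occ, lab)
            np.savetxt(out / f"fraction_{lab}.tsv", F, fmt="%.6f", delimiter="\t")
            save(f"fraction_{lab}", out / f"fraction_{lab}.tsv")
        point, std = overlap_uncertainty(
            proj, config.grid, config.min_count, n_boot=config.n_boot, seed=config.seed
        )
        point.to_csv(out / "overlap.tsv", sep="\t", float_format="%.4f")
        std.to_csv(out / "overlap_std.tsv", sep="\t", float_format="%.4f")
        save("overlap", out / "overlap.tsv")
        if len(projections) >= 2:
            ent = entropy_across_replicates(projections, config.grid, config.min_count)
            ent.to_csv(out / "entropy.tsv", sep="\t", float_format="%.6f")
            save("entropy", out / "entropy.tsv")
        return occ

    occ = _stats()

    @_stage("observables")
    def _observables():
        rg = radius_of_gyration(pooled.xyz)
        write_observable_track("rg", rg, out / "rg.tsv")
        save("rg", out / "rg.tsv")
        score = smoothness_score(proj, rg)
        (out / "smoothness.tsv").write_text(f"observable\tscore\nrg\t{score:.6f}\n")
        save("smoothness", out / "smoothness.tsv")
        return rg

    rg = _observables()

    @_stage("lcs")
    def _lcs():
        density = kde_density(proj)
        if config.lcs_regions:
            regions = config.lcs_regions
        else:
            # default: a disc around the densest point wide enough to hold
            # a tenth of the conformations
            center = proj.coords[int(np.argmax(density))]
            dists = np.linalg.norm(proj.coords - center, axis=1)
            regions = [{"radius": float(np.percentile(dists, 10))}]
        for i, region in enumerate(regions):
            sel = RegionSelection(
                indices=tuple(region["indices"]) if "indices" in region else None,
                polygon=tuple(map(tuple, region["polygon"])) if "polygon" in region else None,
                radius=region.get("radius"),
            )
            idx = sel.resolve(proj, density)
            res = extract_lcs(
                pooled,
                idx,
                n_neighbors=min(config.lcs_n_neighbors, idx.size - 1),
                contact_cutoff=config.lcs_contact_cutoff,
                exclude_adjacent=config.exclude_adjacent,
            )
            res.write(out / f"lcs_{i:02d}.tsv", labels=pooled.labels)
            np.savetxt(out / f"lcs_{i:02d}_contacts.tsv", res.contacts, fmt="%.4f", delimiter="\t")
            members = ConformationEnsemble(
                label=f"lcs_{i:02d}", xyz=pooled.xyz[np.sort(res.member_indices)]
            )
            write_pdb(members, out / f"lcs_{i:02d}.pdb")
            save(f"lcs_{i:02d}", out / f"lcs_{i:02d}.tsv")
        return density

    density = _lcs()

    sector_artifacts = None
    if config.sector_system is not None:

        @_stage("sectors")
        def _sectors():
            spec = SectorSystemSpec(**config.sector_system)
            ensemble, truth = generate_sector_system(spec)
            geometry = spec.default_geometry()
            com = center_of_mass(ensemble.xyz, spec.globular_slice)
            trace = assign_sectors(com, spec.reference_particle(), geometry)
            trace.write(out / "sector_trace.tsv")
            occup = sector_occupancy(trace)
            with open(out / "sector_occupancy.tsv", "w") as fh:
                fh.write("sector\tpercent\n")
                for s, pct in enumerate(occup):
                    fh.write(f"{s}\t{pct:.4f}\n")
            save("sector_trace", out / "sector_trace.tsv")
            save("sector_occupancy", out / "sector_occupancy.tsv")
            return ensemble, truth, trace

        sector_artifacts = _sectors()

    if config.figures:

        @_stage("figures")
        def _figures():
            from . import plotting

            figdir = out / "figures"
            figdir.mkdir(exist_ok=True)
            plotting.scatter_by_observable(proj, rg, figdir / "projection_rg.png", label="Rg (Å)")
            plotting.scatter_by_label(proj, figdir / "projection_models.png")
            plotting.density_figure(proj, density, figdir / "projection_density.png")
            for lab in occ.labels:
                plotting.fraction_map_figure(occ, lab, proj, figdir / f"fraction_{lab}.png")
            save("figures", figdir)

        _figures()

    manifest = {
        "confscape_version": __version__,
        "seed": config.seed,
        "n_conformations": int(pooled.n_conformations),
        "n_residues": int(pooled.n_residues),
        "models": {lab: int(s.stop - s.start) for lab, s in pooled.offsets.items()},
        "input_digest": _digest(pooled.xyz),
        "config": config._as_dict(),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
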