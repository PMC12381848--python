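# confscape

Differential conformational-landscape analysis for intrinsically disordered
protein (IDP) ensembles.

An IDP does not fold into one structure; it functions as a heterogeneous
ensemble of conformations. Comparing several such ensembles — say, a
wild-type histone tail against post-translationally modified variants, or a
linker histone in different nucleosome-binding modes — requires placing all
of them in **one shared ("effective") conformational space** so that
occupancy, exclusivity and heterogeneity can be compared directly.
`confscape` implements that workflow end to end for Cα (or single-bead)
trajectories.

## The method

1. **Dissimilarity.** Every pair of conformations (k, l) is compared through
   all internal Cα–Cα distances with the structural-similarity order
   parameter

   Q_w(k,l) = (1/N_p) Σ_{i<j} exp[ −(r_ij^k − r_ij^l)² / (2 σ_ij²) ],
   σ_ij = |i−j|^0.15 (Å),

   and the dissimilarity δ(k,l) = 1 − Q_w(k,l) ∈ [0, 1). Internal distances
   make δ exactly invariant under rigid motion — no superposition is needed.
2. **Projection.** The pooled δ matrix is embedded in 2D by the iterative
   force scheme: each sweep moves every point toward/away from every other
   so planar distance approaches δ. Runs are seeded and replicated to
   quantify layout noise.
3. **Comparison statistics** on a 27 × 27 grid over the shared projection:
   - *relative fraction* F_ij^w = n_ij^w / N_ij — occupancy proportion of
     model w in bin (i,j); F = 1 marks exclusively populated regions;
   - *density overlap* O^{w,z} = Σ_ij f_ij^w f_ij^z with f^w the
     L2-normalized fraction surface — 1 for identical distributions, 0 for
     disjoint ones (bootstrap standard errors provided);
   - *projection entropy* H^w = −Σ_ij p_ij^w ln p_ij^w, normalized by
     H_max = ln 729 ≈ 6.59 — a heterogeneity proxy, reported as mean ± std
     over replicate projections.
4. **Local conformational signatures (LCS).** Any region of the projection
   is summarized by its distance-RMSD medoid plus the n nearest members and
   a Cα contact-frequency map.
5. **Binding sectors.** For a chain bound to a disc-shaped reference
   particle, every frame is assigned to one of eight cylindrical sectors
   (sector 0 = unbound; sectors 1–7 = azimuthal wedges with sector 1 on the
   dyad axis) from the tracked center of mass, giving occupancy frequencies
   and sector-stratified projections.

Because MD trajectories of the original systems are not redistributable, the
package ships a synthetic-data module: self-avoiding biased random walks
with a tunable collapse bias (compactness → Rg), optional exclusive contact
motifs (e.g. a zipped hairpin) enforced exactly, and a three-domain chain
that tours scheduled sectors around a reference particle, with ground-truth
labels for recovery tests.

## Worked example

```python
from confscape import (
    pool, dissimilarity_matrix, replicate_projections,
    bin_projection, overlap_table, projection_entropy,
)
from confscape.synthetic import tail_study_specs, generate_polymer_ensemble

specs = tail_study_specs(seed=1)            # six 26-residue models
ens = [generate_polymer_ensemble(s, 400, label=k) for k, s in specs.items()]
pooled = pool(ens)                          # 2400 conformations, one space
delta = dissimilarity_matrix(pooled)        # 2400 x 2400, delta in [0, 1)
projs = replicate_projections(delta, 10, base_seed=1001, labels=pooled.labels)
occ = bin_projection(projs[0])              # 27 x 27 grid
print(overlap_table(occ).loc["WT", "A1a"])
print(projection_entropy(occ, "WT")["normalized"])
```

Running the numbered drivers reproduces the full analysis; their actual
output on the bundled study conditions:

```text
$ python analysis/03_landscape_statistics.py
A1a: 1 contiguous region(s) with relative fraction 1 hold 92.8% of its conformations
lowest density overlap: WT-A1a = 0.000 ± 0.000
normalized projection entropy (mean ± std over replicates):
  A1a   0.620 ± 0.011
  ...
  WT    0.796 ± 0.006
narrowest: A1a; broadest: WT

$ python analysis/05_binding_sectors.py
1000 frames; ground-truth sector recovery 100.0%
occupancy: sector 0: 10.1%, sector 1: 78.3%, sector 2: 9.8%, sector 3: 1.3%, sector 7: 0.5%
sectors 4, 5, 6 were not visited
```

Read: the hairpin-stabilized model (A1a) owns a contiguous exclusively
populated region holding 92.8% of its conformations, shares the least
conformational space with every other model, and is the least heterogeneous
(lowest normalized entropy), while the unconstrained wild type is the most
heterogeneous — exactly the structure engineered into the synthetic study
conditions. The sector analysis recovers every scheduled binding mode and
its occupancy percentages from coordinates alone.

The same pipeline is scriptable from the shell:

```bash
confscape all -c config.yaml          # or the staged subcommands:
confscape dissim|project|analyze|lcs|sectors -c config.yaml
```

## Layout

- `src/confscape/` — the library: `synthetic`, `ensembles`, `dissimilarity`,
  `projection`, `landscape`, `lcs`, `sectors`, `metrics`, `pipeline`,
  `plotting`, `cli`.
- `analysis/01…05_*.py` — numbered narrative drivers writing tables and
  figures under `results/`.
- `tests/` — unit, property and end-to-end acceptance tests.
- `docs/methods.md` — model assumptions, parameter choices, and limitations.
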