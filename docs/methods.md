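# Methods

## Dissimilarity metric

The pairwise dissimilarity is δ(k,l) = 1 − Q_w(k,l), with

Q_w(k,l) = (1/N_p) Σ_{i<j} exp[ −(r_ij^k − r_ij^l)² / (2 σ_ij²) ],  σ_ij = |i−j|^0.15 Å.

Q_w is a Gaussian-weighted agreement of all internal Cα–Cα distances: it is
1 exactly when the internal geometry is identical and decays toward 0 as
structures diverge, with the sequence-separation weight σ_ij loosening the
comparison for distant residue pairs. Consequences worth knowing:

- δ is symmetric, has an exactly zero diagonal, lies in [0, 1), and is
  invariant under rigid rotation/translation of either conformation (only
  internal distances enter). These invariants are asserted in tests against
  a term-by-term scalar oracle.
- σ is of order 1–2 Å, so *any* flexible ensemble has substantial internal
  dissimilarity (δ ≈ 0.5 between two samples of the same disordered chain).
  Engineered contact motifs therefore produce clusters that are distinct
  from, rather than orders of magnitude tighter than, the background — which
  is also how real IDP sub-states behave under this metric.
- **Pair set.** All i < j pairs are used, including |i−j| = 1. At fixed bond
  length adjacent pairs contribute a constant 1 to the sum; an
  `exclude_adjacent` flag removes short-range pairs for sensitivity checks.
  The flag is honored consistently by the distance-RMSD used for LCS
  extraction.
- The matrix is computed densely in double precision, row-vectorized, with a
  configurable memory cap (default 6 GiB) that refuses oversized requests
  with a clear message rather than thrashing.

## Force-scheme projection

Points start uniformly in the unit square (seeded) and are refined for 100
full sweeps. In each sweep the points are visited in random order; with
anchor p fixed, every other point q moves along the line p→q by
lr · (δ(p,q) − d2D(p,q)) / d2D, with the learning rate decaying linearly
from 0.12 to 0.01 and an ε = 1e-9 guard for coincident points. These
constants are free parameters of the technique and are exposed in the
configuration; the defaults were chosen for stable convergence at desk
scale (10²–10⁴ points).

- **Monotone safeguard.** Per-anchor sweeps do not guarantee monotone
  stress. Every checkpoint (10 sweeps), the residual stress
  Σ_{k<l} (d2D − δ)² is evaluated; if it exceeded the previous checkpoint,
  the block is rolled back and re-run with a halved step scale (twice at
  most, else the previous coordinates are kept). Recorded stress is
  therefore non-increasing by construction, and the damping only engages
  where the raw iteration would have oscillated.
- **Replicates, not determinism claims.** The layout depends on the seed;
  scientific statements are made on statistics aggregated over replicate
  projections (default 10; seeds base, base+1, …). Replicate layouts
  correlate strongly in their pairwise-distance structure on well-separated
  inputs (Pearson > 0.9 in tests).
- Labels never enter the layout (asserted by a shuffle test).
- The numba-jitted sweep kernel and the pure-numpy fallback implement the
  same update; numba is used when available for a ~50× speedup.

## Grid statistics

A regular grid (default 27 × 27, giving H_max = ln 729 ≈ 6.59) spans the
tight bounding box of the projection; intervals are half-open except the
final edge, so every point is binned exactly once. Bins with pooled count
below `min_count` (default 3 — the exclusion threshold for "poor
statistics" is not canonical and is config-exposed) are masked invalid for
the fraction and overlap statistics.

- **Relative fraction** F_ij^w = n_ij^w / N_ij on valid occupied bins;
  Σ_w F_ij^w = 1 exactly per bin. Exclusive regions are connected
  components (4-neighborhood) of bins with F = 1.
- **Density overlap** uses the L2 (cosine) normalization
  f^w = F^w / √(Σ F²): the unique reading under which O^{w,w} = 1 holds
  identically, O is symmetric, and disjoint supports give exactly 0.
  Uncertainties come from bootstrap resampling of conformations within each
  model (grid edges held fixed); replicate-projection spread would be an
  equally defensible error source, and the bootstrap is labeled as the
  package's choice.
- **Projection entropy** uses each model's own occupancy distribution over
  all occupied bins (0·ln 0 ≡ 0), normalized by ln(bin count). The
  poor-statistics mask is *not* applied by default (entropy is a property
  of the model's own distribution, not of cross-model comparison); a
  `valid_only` flag exists. Merging bins never increases H (tested).
  Entropy is reported as mean ± std across replicate projections.
- KDE point density uses `scipy.stats.gaussian_kde` with Scott's rule by
  default, bandwidth config-exposed; it ranks high-density regions for LCS
  seeding.

## Local conformational signatures

A region (explicit indices, a polygon in projection coordinates, or a disc
around the densest point) is summarized by the conformation minimizing the
mean distance-RMSD

dRMSD(k,l) = √( (1/N_p) Σ_{i<j} (r_ij^k − r_ij^l)² )

over the selection (exhaustive search; ties break to the lowest global
index), shown with its n nearest members (default 30; 20 is conventional
for longer chains) and a contact map (frequency of r_ij ≤ 8 Å, the cutoff
being config-exposed; diagonal set to 1 by convention). Any superposition
for display is least-squares alignment to the medoid and affects no
statistic.

## Binding sectors

The reference particle's frame comes from its principal axes: axial = the
smallest-extent axis (a disc's symmetry axis), dyad = the largest-extent
axis oriented toward the bead farthest from the centroid (deterministic).
Sector 0 collects frames whose tracked center of mass (uniform bead masses;
only Cα coordinates exist) lies beyond the unbound radial threshold
(default: particle radius + 20 Å, in the disc plane); otherwise the azimuth
selects one of seven equal wedges, sector 1 centered on the dyad. Exact
boundary geometry is not canonical; it is fully config-driven (custom
azimuth intervals are validated to partition the circle), and the default
reproduces the qualitative eight-sector scheme.

## Synthetic data: what it emulates and what it does not

The generator grows self-avoiding biased random walks: bead m is placed at
fixed bond length (3.8 Å) from bead m−1, the step direction biased toward
the centroid of the placed beads with strength proportional to
`compactness` (gain 1.0 at compactness 1, calibrated so mean Rg of a
26-residue chain falls smoothly from ≈ 8.8 Å at 0 to ≈ 4.2 Å at 0.9).
Excluded volume (2.0 Å between nonbonded beads) is enforced by direction
resampling. Exclusive contact motifs are enforced exactly: growth is guided
by a pull toward the partner bead that ramps up as the remaining bond
budget shrinks — producing tight, well-defined contact modes — and frames
still violating a constraint afterwards are fixed by a constraint-relaxation
pass (pull open pairs together, push excluded-volume clashes apart,
re-project bonds to exact length) with rejection-regeneration as the final
fallback (cap 10,000 attempts per frame, then an error naming the pair).
All randomness flows from a single seeded generator: identical spec + seed
gives bitwise-identical coordinates.

The six-model study conditions (`tail_study_specs`) emulate a wild-type
disordered tail versus five modified variants under the premise that each
modification stabilizes specific transient intramolecular contacts:

| model | constraint set | role |
|-------|----------------|------|
| WT    | none (compactness 0.5) | broadest ensemble |
| A1a   | six nested hairpin contacts at 6 Å, compactness 0.45 | tight exclusive mode, narrowest |
| A1b / A2 | one stabilized loop (two contacts, 6.5 Å) in the N-/C-half | mildly narrowed |
| A3    | both terminal halves looped (three contacts) | narrowed |
| A4    | two separate internal loops (6 Å) | narrowed |

All models share chain length, bond length and collapse bias, so detected
differences come from contact structure, not trivial size effects. Effect
sizes were calibrated once, at design time, so that the engineered structure
is recoverable with margin across seeds and replicate projections; they are
frozen as the module's defaults. The sector-system chain is one bonded walk
(three domains; the middle domain grown with high collapse bias) rigidly
translated so the globular center of mass sits inside the scheduled sector,
at least 20% of a wedge's half-width away from its azimuthal boundaries —
hence round-trip recovery is expected to be essentially exact, and ≥ 99% is
asserted.

What the generator does **not** emulate: force-field physics, solvent,
temperature, acetylation chemistry, kinetics or time correlation between
frames (frames are i.i.d. draws, so burn-in/stride subsampling only
exercises bookkeeping), and realistic nucleosome geometry beyond a rigid
disc. Passing tests therefore demonstrate that the *analysis* recovers
engineered landscape structure from Cα coordinates; they say nothing about
the biological systems themselves.

## Problem sizes

Default study conditions: 6 models × 400 frames (2400 pooled conformations,
a 2400² dissimilarity matrix), 10 replicate projections of 100 sweeps, and
a 1000-frame sector system. The subsampling analysis generates six
88,000-frame trajectories (burn-in 4000, stride 14 → 6000 each, 36,000
pooled). These sizes run in minutes on one CPU and were chosen as the
package's desk-scale defaults; every count scales linearly through the
configuration.

## Known limitations

- The force scheme is O(N² ) per sweep and the δ matrix O(N²) in memory;
  beyond ~2·10⁴ conformations, subsample first (the memory guard enforces
  this deliberately).
- Projection entropy and overlap depend on the layout realization; always
  read them with their replicate or bootstrap spread.
- Grid statistics depend on `min_count` near the point-cloud border; the
  default (3) suppresses border artifacts at the cost of discarding sparse
  bins entirely.
- The multi-model PDB reader supports plain Cα/single-bead topologies
  without insertion codes — simulated input only.
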