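"""Differential statistics over the shared projection.

Reads the replicate projections written by 02_project_landscape.py and
computes, on the 27x27 grid: per-model relative-fraction maps (exclusively
populated regions), the density-overlap table with bootstrap standard
errors, and the normalized projection entropy (mean ± std across the 10
replicates).  States which model owns the exclusive mode, which pair of
models shares the least space, and how heterogeneity ranks.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from confscape import plotting
from confscape.landscape import (
    bin_projection,
    entropy_across_replicates,
    exclusive_coverage,
    exclusive_regions,
    overlap_uncertainty,
    relative_fraction_map,
)
from confscape.projection import Projection

SEED = 1
N_REPLICATES = 10
OUT = Path("results")
EXCLUSIVE_MODEL = "A1a"


def load_projection(i: int) -> Projection:
    t = pd.read_csv(OUT / f"projection_{i:02d}.tsv", sep="\t")
    return Projection(coords=t[["x", "y"]].to_numpy(), labels=t["label"].to_numpy())


def main() -> None:
    projs = [load_projection(i) for i in range(N_REPLICATES)]
    proj = projs[0]
    occ = bin_projection(proj)

    for lab in occ.labels:
        F = relative_fraction_map(occ, lab)
        np.savetxt(OUT / f"fraction_{lab}.tsv", F, fmt="%.6f", delimiter="\t")
        plotting.fraction_map_figure(occ, lab, proj, OUT / "figures" / f"fraction_{lab}.png")
    _, n_comp = exclusive_regions(occ, EXCLUSIVE_MODEL)
    cov = exclusive_coverage(occ, proj, EXCLUSIVE_MODEL)
    print(f"{EXCLUSIVE_MODEL}: {n_comp} contiguous region(s) with relative fraction 1 "
          f"hold {100*cov:.1f}% of its conformations")

    point, std = overlap_uncertainty(proj, n_boot=50, seed=SEED)
    point.to_csv(OUT / "overlap.tsv", sep="\t", float_format="%.4f")
    std.to_csv(OUT / "overlap_std.tsv", sep="\t", float_format="%.4f")
    mat = point.to_numpy().copy()
    np.fill_diagonal(mat, 2.0)
    a, b = np.unravel_index(np.argmin(mat), mat.shape)
    print(f"lowest density overlap: {point.index[a]}-{point.columns[b]} = "
          f"{mat[a, b]:.3f} ± {std.iloc[a, b]:.3f}")

    ent = entropy_across_replicates(projs)
    ent.to_csv(OUT / "entropy.tsv", sep="\t", float_format="%.6f")
    ranked = ent["mean_normalized_entropy"].sort_values()
    print("normalized projection entropy (mean ± std over replicates):")
    for lab, v in ranked.items():
        print(f"  {lab:5s} {v:.3f} ± {ent.loc[lab, 'std_normalized_entropy']:.3f}")
    print(f"narrowest: {ranked.index[0]}; broadest: {ranked.index[-1]}")


if __name__ == "__main__":
    main()
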