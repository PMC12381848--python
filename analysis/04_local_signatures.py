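"""Local conformational signatures of the projected landscape.

Extracts two LCSs from the first replicate projection: one seeded at the
globally densest point (the landscape's dominant basin) and one inside the
exclusive hairpin region, then summarizes each by its Cα contact map.  The
hairpin LCS should consist purely of hairpin-model members and show the
zipped contacts at unit frequency.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from confscape import plotting
from confscape.ensembles import ConformationEnsemble, pool, write_pdb
from confscape.landscape import kde_density
from confscape.lcs import RegionSelection, extract_lcs
from confscape.projection import Projection
from confscape.synthetic import generate_polymer_ensemble, tail_study_specs

SEED = 1
N_FRAMES = 400
OUT = Path("results")


def main() -> None:
    specs = tail_study_specs(seed=SEED)
    pooled = pool([generate_polymer_ensemble(s, N_FRAMES, label=k) for k, s in specs.items()])
    t = pd.read_csv(OUT / "projection_00.tsv", sep="\t")
    proj = Projection(coords=t[["x", "y"]].to_numpy(), labels=t["label"].to_numpy())
    density = kde_density(proj)

    # LCS 1: densest region of the whole landscape
    center = proj.coords[int(np.argmax(density))]
    radius = float(np.percentile(np.linalg.norm(proj.coords - center, axis=1), 5))
    top = extract_lcs(pooled, RegionSelection(radius=radius).resolve(proj, density), n_neighbors=30)
    top.write(OUT / "lcs_top_density.tsv", labels=pooled.labels)
    np.savetxt(OUT / "lcs_top_density_contacts.tsv", top.contacts, fmt="%.4f", delimiter="\t")
    plotting.contact_map_figure(top.contacts, OUT / "figures" / "lcs_top_density_contacts.png")
    lab = pooled.labels[top.medoid_index]
    print(f"top-density LCS: medoid {top.medoid_index} (model {lab}), "
          f"mean dRMSD {top.mean_drmsd:.2f} Å over {top.selection_indices.size} members")

    # LCS 2: the exclusive hairpin mode
    hairpin_idx = pooled.indices_of("A1a")
    hp_center = proj.coords[hairpin_idx].mean(axis=0)
    hp_radius = float(np.percentile(
        np.linalg.norm(proj.coords[hairpin_idx] - hp_center, axis=1), 50
    ))
    sel = np.flatnonzero(np.linalg.norm(proj.coords - hp_center, axis=1) <= hp_radius)
    hp = extract_lcs(pooled, sel, n_neighbors=30)
    hp.write(OUT / "lcs_hairpin.tsv", labels=pooled.labels)
    np.savetxt(OUT / "lcs_hairpin_contacts.tsv", hp.contacts, fmt="%.4f", delimiter="\t")
    plotting.contact_map_figure(hp.contacts, OUT / "figures" / "lcs_hairpin_contacts.png")
    members = pooled.labels[hp.member_indices]
    purity = float(np.mean(members == "A1a"))
    zipped = [hp.contacts[i, 25 - i] for i in (1, 3, 5, 7, 9, 11)]
    print(f"hairpin-region LCS: {100*purity:.0f}% of members from A1a; "
          f"zipped-contact frequencies {['%.2f' % z for z in zipped]}")
    write_pdb(
        ConformationEnsemble(label="lcs_hairpin", xyz=pooled.xyz[np.sort(hp.member_indices)]),
        OUT / "lcs_hairpin.pdb",
    )


if __name__ == "__main__":
    main()
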