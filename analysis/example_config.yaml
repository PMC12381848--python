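# Example run configuration for the `confscape` CLI.
#   confscape all -c analysis/example_config.yaml
# Stages can also be run separately: generate, dissim, project, analyze,
# lcs, sectors (dissim caches the expensive matrix for the later stages).
seed: 1
output_dir: results/cli_demo
models:
  - label: WT
    synthetic: {n_residues: 26, compactness: 0.5, seed: 1}
    n_frames: 200
  - label: A1a
    synthetic:
      n_residues: 26
      compactness: 0.45
      exclusive_motif: [[1, 24, 6.0], [3, 22, 6.0], [5, 20, 6.0], [7, 18, 6.0], [9, 16, 6.0], [11, 14, 6.0]]
      seed: 2
    n_frames: 200
  - label: A2
    synthetic:
      n_residues: 26
      compactness: 0.5
      exclusive_motif: [[10, 23, 6.5], [13, 20, 6.5]]
      seed: 3
    n_frames: 200
discard: 0
stride: 1
n_replicates: 5
max_iter: 100
grid: [16, 16]          # coarser than the 27x27 default: only 600 points here
min_count: 3
n_boot: 30
lcs_n_neighbors: 30
lcs_contact_cutoff: 8.0
sector_system:
  n_nter: 12
  n_globular: 25
  n_cter: 12
  sector_schedule: [[1, 783], [0, 101], [2, 98], [3, 13], [7, 5]]
  seed: 12
figures: true
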