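# Full simulate-mode pipeline configuration with defaults spelled out.
mode: simulate            # or "table" with input_path pointing at a TSV
out_dir: out
seed: 7

design:
  conditions:
    - H3_1-20_unmod
    - H3K9me3
    - H3S10ph
    - H3K9me3S10ph
    - H3_18-38_unmod
    - H3K27me3
    - H3S28ph
    - H3K27me3S28ph
    - beads
  replicates: 2
  beads_condition: beads

generator:
  use_library: true       # 8 archetype complexes; or give "complexes:" explicitly
  n_background: 300
  noise_cv: 0.2
  background_binding: 0.05
  detection_midpoint: -3.1
  detection_slope: 2.0
  apply_detection: true

network:
  beta: 15
  candidate_betas: [2, 4, 6, 8, 10, 12, 15, 18]
  min_module_size: 5
  cut_fraction: 0.99
  split_ratio: 0.5
  static_cut_height: null

ingest:
  min_ratio_count: 2
  max_missing: 14

stats:
  two_sided: false
  leave_one_out: false
  fdr: none               # or benjamini_hochberg
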