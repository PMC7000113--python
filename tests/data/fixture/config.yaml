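n_proteins: 20
fraction_changed: 0.25
precursors_per_protein:
- 2
- 3
groups:
  A: 0.0
  B: 1.0
replicates_per_group: 3
baseline_log2_mean: 14.0
baseline_log2_spread: 1.5
precursor_offset_spread: 1.0
level_offset_spread: 1.0
sigma_bio: 0.3
sigma_ms1: 0.2
sigma_ms2: 0.2
interference_prob: 0.1
interference_max_fraction: 1.0
interference_levels:
- 1
- 2
ms1_floor: 100.0
seed: 42
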