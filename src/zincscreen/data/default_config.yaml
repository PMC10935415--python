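# Default pipeline configuration. Every threshold is the printed default of
# the screening workflow; overrides are recorded in each stage's manifest.
seed: 0

synthetic:
  n_ligands: 208
  high_fraction: 0.6298076923692  # 131/208
  lg_ki_range: [-4.0, 7.0]
  dup_entry_rate: 0.20
  discordant_rate: 0.15
  near_dup_rate: 0.10
  n_informative_descriptors: 8
  n_noise_descriptors: 40
  effect_size: 1.5
  noise_sd: 1.0
  library_size: 2000
  library_active_fraction: 0.05

curation:
  similarity_threshold: 0.75
  modeling_fraction: 0.7932692307692307  # 165/208
  inner_train_fraction: 0.7

descriptors:
  activity_r_min: 0.15
  pairwise_r_max: 0.8
  correlation: pearson

selection:
  method: cfs_wrapper
  wrapper_folds: 5

classifiers:
  algorithm: nb
  ibk_k: [1, 5, 25]
  j48_min_obj: [2, 4, 8]
  oner_min_bucket: 6

evaluation:
  cv_folds: 10
  cv_repeats: 10
  n_replicates: 10

gate:
  multiplier: 1.96
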