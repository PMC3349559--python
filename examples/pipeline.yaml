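# Full synthetic tag-DGE pipeline: five staged libraries (a non-swelling
# mutant baseline plus four developmental stages), cleaned, mapped and tested
# over the six staged comparisons.  All randomness flows from `seed`.
seed: 7
design:
  n_genes: 1000
  gene_length_range: [200, 2000]
  library_depth: 200000
  de_fraction: 0.10
  fold_change_range: [2.0, 16.0]
  error_rate: 0.001
  adaptor_only_rate: 0.008
  n_read_rate: 0.0001
  taggable_fraction: 0.95
annotation: synthetic
parameters:
  max_mismatch: 1
  min_copy: 2
  fdr_threshold: 0.001
  log2_threshold: 1.0
  extreme_threshold: 10.0
  cluster_k: 4
  alpha: 0.05
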