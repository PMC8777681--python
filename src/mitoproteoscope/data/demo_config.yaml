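# Demo end-to-end run on synthetic data (small sizes; finishes in seconds).
seed: 42
simulate:
  n_proteins: 800
  n_terms: 30
  term_size_range: [10, 30]
differential:
  variant: student
  fc_log2: 1.0
  p_max: 0.05
rca:
  ci_level: 0.95
enrich:
  query: nominal_down
  min_term_size: 5
assays:
  images_per_group: 2
report: true
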