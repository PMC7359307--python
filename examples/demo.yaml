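# End-to-end demo: simulate three strains from a recent split and run the
# full QC -> statistics -> scans -> candidates chain.
simulation:
  mode: split
  n_pops: 3
  pop_size: 100
  seq_length: 400000
  mutation_rate: 2.0e-6
  n_diploids_per_pop: 30
  split_generations: 9
seed: 42
scan_threshold: bonferroni
make_plots: true
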