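# Desk-scale synthetic cohort analysis: a 400-knee, 40-feature mixed-type
# matrix with four planted phenotype blocks, four pain trajectories, and
# bicluster-linked progression outcomes.  Completes in a few minutes on
# one CPU and is bit-reproducible under a fixed seed.
output_dir: results/synthetic_desk
synthetic_spec: default
seed: 0
n_rows: 400
n_cols: 40
delta: 0.2
max_k: 6
min_rows: 2
sigclust:
  n_sim: 150
  restarts: 10
  seed: 0
gbtm:
  G_max: 3
  seed: 0
  dropout: true
  n_starts: 3
figures: true
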