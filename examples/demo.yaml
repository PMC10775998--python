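# Small demonstration run against the synthetic oracle (~30 s on one CPU).
# The seed controls every stochastic component; rerunning with the same
# config reproduces the metrics byte for byte.
seed: 7
n_seed_sequences: 64
ga:
  n_steps: 60
  n_trials: 6
  n_children: 16
  wave_size: 8
gp:
  composition_weights: [1.0, 0.3]
al:
  n_ehvi_rounds: 3
  rf_trees: 50
oracle:
  noise_b2_rel: 0.05
  noise_d_rel: 0.05
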