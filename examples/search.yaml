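task: search
seed: 7
session_id: search
agent: {preset: M1}
session:
  n_runs: 2
  n_init_trials: 10
  n_test_trials: 100
  set_sizes: [3, 6, 9, 12]
  set_size_policy: stratified
  n_shared: 1
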