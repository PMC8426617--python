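task: learning
seed: 7
session_id: learning
agent: {params: {alpha: 0.3, beta: 5.0}}
session:
  n_blocks: 40
  block_len_range: [45, 60]
  n_objects: 3
  n_varied_dims: 1
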