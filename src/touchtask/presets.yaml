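# Synthetic-agent presets. The RT presets target per-distractor slopes of
# roughly 0.05-0.07 s and intercepts of roughly 0.77-0.91 s; the learning
# presets target criterion at roughly trial 12-19 with a 75-80% plateau.
# These are simulation presets, not measurements.
rt_agents:
  M1: {p_correct: 0.875, b0: 0.905, b1: 0.072, sigma: 0.15, lapse_rate: 0.02}
  M2: {p_correct: 0.902, b0: 0.879, b1: 0.057, sigma: 0.15, lapse_rate: 0.02}
  M3: {p_correct: 0.812, b0: 0.770, b1: 0.049, sigma: 0.15, lapse_rate: 0.02}
rl_agents:
  L1: {alpha: 0.40, beta: 6.0, v0: 0.0}
  L2: {alpha: 0.30, beta: 5.0, v0: 0.0}
  L3: {alpha: 0.25, beta: 5.0, v0: 0.0}
  L4: {alpha: 0.20, beta: 4.5, v0: 0.0}
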