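# touchtask

Headless simulator and analysis toolkit for touchscreen cognitive tasks:
visual search with a set-size manipulation and block-wise feature-reward
learning, driven by synthetic agents instead of a live subject.

The package models:

- **Stimulus space** (`touchtask.stimulus_space`) — a combinatorial object
  space of four feature dimensions (9 body shapes × 8 colors × 11 arm types
  × 9 surface patterns = 7,128 objects), each dimension with one designated
  *neutral* (never rewarded) value, plus a CIELAB palette generator with
  equal hue spacing on a fixed-chroma circle and constrained samplers for
  targets, search distractor arrays, and learning arrays.
- **Task engine** (`touchtask.task_engine`) — seeded generators for session
  plans (search: runs of 10 initialization + 100 test trials; learning:
  40 blocks of 45–60 trials with a switching rewarded feature) and a
  discrete-event trial state machine with outcome classification
  (correct / incorrect / abort on the fully neutral object / timeout),
  a Touch-Hold-Release difficulty ladder, and touch-trace classification.
- **Agents** (`touchtask.agents`) — a linear-RT search responder
  (RT = b0 + b1·set_size + noise) and a delta-rule feature learner with
  softmax choice. Parameter presets live in `src/touchtask/presets.yaml`.
- **Analysis** (`touchtask.analysis`) — per-set-size RT summaries and the
  OLS set-size regression (slope = set-size effect, intercept = baseline
  speed), trials-to-criterion (70% over a 10-trial trailing window by
  default), plateau accuracy, learning curves, and weekly (5-session)
  aggregation.
- **I/O & CLI** (`touchtask.io_cli`) — YAML run configs, append-only
  JSON-Lines trial logs flushed per trial (crash-safe), CSV export, and the
  command-line interface.

## CLI

```sh
# simulate: generate a plan, run the configured agent, write the trial log
touchtask simulate --config examples/search.yaml --seed 7 --out out/

# analyze: per-session summaries, regression fit, block statistics
touchtask analyze --log out/search.jsonl --out out/ --criterion 0.70 --window 10

# report: weekly (default 5-session) aggregates over many session summaries
touchtask report --in out/ --out report/ --sessions-per-week 5
```

A minimal search config:

```yaml
task: search
seed: 7
agent: {preset: M1}
session: {n_runs: 2, n_test_trials: 100, set_sizes: [3, 6, 9, 12]}
```

and a learning config:

```yaml
task: learning
seed: 7
agent: {params: {alpha: 0.3, beta: 5.0}}
session: {n_blocks: 40, block_len_range: [45, 60], n_varied_dims: 1}
```

Identical `(config, seed)` pairs produce byte-identical logs.

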