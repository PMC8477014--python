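# Minimal end-to-end run: one simulated day, logistic model only.
#   ethoclock run-all --config examples/demo.yaml
seed: 1
outdir: runs/demo
simulator:
  preset: default      # default | null | order_only
  n_days: 1
windowing:
  window_len: 100      # samples per window (100 x 3 s = 5 min)
  stride: 100          # non-overlapping windows for a quick demo
models:
  logistic: {}
protocol:
  k: 5
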