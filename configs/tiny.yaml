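# Minimal smoke-test configuration: finishes in ~1 minute on one CPU.
seed: 0
schemes: [two]
phantom:
  n_per_grade: [10, 10, 10, 10, 10]
train:
  epochs: 1
  tl_epochs: 1
  batch_size: 16
  chunk_size: 8
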