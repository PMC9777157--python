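# oagrade

Deep hybrid learning pipeline for grading knee-osteoarthritis severity from
radiographs, exercisable end-to-end on synthetic knee-radiograph phantoms.

The pipeline has two arms:

* **DHL-I** — a bespoke 5-class CNN (input 112×112×1, three 3×3×32 convs →
  maxpool, 3×3×64 → avgpool, 3×3×128 → avgpool, flatten 25088, dense 200;
  5,129,973 parameters) trained from scratch, whose 200-dim penultimate-layer
  activations feed a MinMax → PCA(99% variance) → RBF-SVM (C=1000, γ=0.001)
  head.
* **DHL-II** — transfer-learning variants: the trained conv backbone is
  frozen, a new 512/256/k dense head is fine-tuned for the coarse 4/3/2-class
  grade groupings, and the 256-dim penultimate activations feed the same
  hybrid head.

Because the OAI radiograph collection is not redistributable, the package
ships a phantom generator whose images vary monotonically with severity
grade (joint-space narrowing, osteophyte blobs, sclerosis bands), making
every stage testable offline. The CNN kernel (convolution, pooling, dropout,
Adam, backprop) is implemented in NumPy — no deep-learning framework is
required.

## CLI

```sh
oagrade run-all --config configs/tiny.yaml --seed 0 --out runs/demo
```

Subcommands (`--help` on each): `generate-data`, `preprocess`, `split`,
`train-base`, `train-tl --scheme {four,three,two}`, `extract-features`,
`fit-dhl`, `evaluate`, `run-all`. All stages share a run directory and every
JSON artifact embeds the config hash and seed. Config is YAML/JSON; defaults
are the published hyperparameters (CLAHE clip 5.0 tiles 8×8, 80/20 split with
a 10% validation carve-out, Adam 0.001/0.9/0.999, batch 256, 50 base /
20 fine-tune epochs, PCA target 0.99, SVM C=1000 γ=0.001), so an override-free
run is the published recipe at phantom scale. A minimal config:

```yaml
seed: 0
schemes: [two, three]
phantom: {n_per_grade: [20, 20, 20, 20, 20]}
train: {epochs: 2, tl_epochs: 2, batch_size: 32}
```

## Layout

| module | role |
| --- | --- |
| `oagrade.phantom` | grade-dependent synthetic radiographs + CSV manifests |
| `oagrade.preprocess` | resize → CLAHE → rescale; stratified hold-out split; grade grouping |
| `oagrade.nn` / `oagrade.cnn` | NumPy NN kernel; base 5-class architecture and training |
| `oagrade.dhl` | deep features → MinMax → PCA → RBF-SVM |
| `oagrade.transfer` | frozen-backbone fine-tuning (512/256/k heads) |
| `oagrade.metrics` | confusion matrix, one-vs-rest metrics, macro averages, ROC/AUC |
| `oagrade.oai_reference` | published OAI benchmark reference values |
| `oagrade.experiment` / `oagrade.cli` | orchestration and command line |
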