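# qsteato

Hybrid quantum-classical classification of hepatic-steatosis histology tiles,
with a federated-learning simulation and a fully synthetic, ground-truthed
data generator.

The package implements:

- **`qsteato.quantum`** — a from-scratch dense statevector simulator
  (little-endian, `R_A(φ) = exp(−iφA/2)`) and the quantum depth-infused (QDI)
  circuit head: a data re-uploading circuit where trainable RX rows +
  CNOT entanglers interleave with RZ feature encodings. The default
  configuration (5 qubits × 20 re-uploading blocks, one initial variational
  row) encodes 100 features with 105 trainable rotation gates. Gradients use
  the exact two-point parameter-shift rule; a vectorized batch engine
  evaluates all shifted circuits for a minibatch in one pass.
- **`qsteato.nn` / `qsteato.models` / `qsteato.training`** — a minimal numpy
  neural-network stack (conv/affine layers, Adam, manual backprop) assembling
  a tiny CPU-friendly CNN backbone (a pretrained ResNet18 adapter is an
  opt-in that requires torch) with either a hybrid head (affine → π·tanh
  squash → QDI → affine) or a structurally matched classical head, trained
  with a class-weighted cross-entropy: the "not-suitable" class weight is a
  penalty multiplier λ ≥ 1, so λ = 1 recovers plain cross-entropy and larger
  λ penalizes false negatives (diseased livers predicted transplantable).
- **`qsteato.datasynth`** — the staging pipeline (fat-fraction → grade 0–3 →
  binary suitability; 1024-px slide tiling with reassembly coordinates;
  258-px center crop) and a deterministic synthetic tile generator: pink
  tissue-textured tiles with white rounded fat droplets driven to a target
  area fraction (grade labels exact by construction) plus irregular
  elongated white confounders excluded from the fat fraction.
- **`qsteato.federated`** — disjoint, class-balanced, equal-size client
  partitions (patient-disjoint when patient ids are present), vanilla
  sample-count-weighted FedAvg, and a sequential round simulation
  (broadcast → local epochs → aggregate → global eval). A single client
  with synchronized seeding reproduces centralized training bit-identically.
- **`qsteato.evaluation` / `qsteato.cli`** — confusion-matrix metrics
  (fn_rate = misses / actual-not-suitable), λ and training-set-size sweeps
  with k-fold CV, heatmap reassembly of per-tile predictions, and a typer
  CLI.

## CLI

Commands compose into a pipeline; every run writes a `resolved_config.yaml`
next to its outputs.

```bash
qsteato synth --out-dir runs/synth --n-per-grade 50 --seed 1    # manifest (+ PNGs with --render)
qsteato train runs/synth/manifest.csv --out-dir runs/train --model-kind hybrid
qsteato evaluate runs/synth/manifest.csv runs/train/model.npz --out-dir runs/eval
qsteato train-fl runs/synth/manifest.csv --clients 4 --rounds 15
qsteato sweep-lambda runs/synth/manifest.csv
qsteato sweep-size runs/synth/manifest.csv
qsteato grid-fl runs/synth/manifest.csv --clients 4,8 --samples 100
qsteato tile slide.png --tile-px 1024
qsteato heatmap preds.csv --out-dir runs/heat
```

Configuration is a single YAML file with `data` / `model` / `train` /
`federated` / `eval` blocks (see `qsteato/config.py` for defaults), passed
via `--config`.

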