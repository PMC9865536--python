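# doaeeg — depth-of-anesthesia estimation from frontal EEG

`doaeeg` estimates a 0–100 sedation-depth index (PSI, 100 ≈ fully awake) from
4-channel frontal EEG. It contains the full pipeline:

* **Synthetic data** with a known depth → spectrum → label structure: four
  frontal channels at 178.2 Hz whose band composition shifts with a latent
  anesthetic depth, contaminated with blink artifacts, 50 Hz line noise and
  slow drift (`doaeeg.synth`).
* **Preprocessing**: 4 s windows (712 samples, 50 % overlap), a 1–51 Hz
  linear-phase FIR bandpass, and ocular-artifact removal chaining wavelet
  band splitting, cross-channel FastICA, sample-entropy + topography
  classification and CEEMDAN-refined subtraction (`doaeeg.preprocess`,
  `doaeeg.emd`).
* **Features**: 14 spectral/entropy features per window — absolute and
  relative band powers, spectral edge frequencies, sample entropy
  (`doaeeg.features`).
* **Models**: a 1-D deep residual shrinkage network with channel-wise learned
  soft thresholds, implemented in NumPy with verified manual backprop
  (`doaeeg.drsn`, `doaeeg.nn`), plus SVR / random-forest / MLP baselines on
  the feature vectors (`doaeeg.baselines`).
* **Evaluation**: PSI regression error, Spearman correlation, and
  macro-averaged one-vs-rest metrics over the four anesthetized states
  (AW/LA/NA/DA), under random or subject-grouped 5-fold cross-validation
  (`doaeeg.evaluate`).

## Quick start

```python
import numpy as np

from doaeeg.drsn import DRSNRegressor, ModelConfig, TrainConfig, train
from doaeeg.evaluate import compute_metrics, standardize
from doaeeg.features import FEATURE_NAMES, extract_features
from doaeeg.preprocess import make_samples
from doaeeg.synth import SimSpec, generate_dataset

# 1. simulate two subjects' contaminated 4-channel recordings
spec = SimSpec(n_subjects=2, duration_per_subject=120.0, seed=0)
subjects = generate_dataset(spec)

# 2. segment + bandpass (skip the slow ocular-artifact removal for the demo)
samples = [s for sub in subjects for s in make_samples(sub, eoa_removal=False)]
x = np.array([s.segment.data for s in samples], dtype=np.float32)
y = np.array([s.psi for s in samples])
print(f"{len(samples)} windows of shape {x.shape[1:]}, PSI {y.min():.0f}-{y.max():.0f}")

# 3. spectral/entropy features of the first window
vec = extract_features(x[0], spec.fs)
for name, v in list(zip(FEATURE_NAMES, vec))[:5]:
    print(f"  {name:28s} {v:8.3f}")

# 4. train the residual shrinkage regressor on a random 80/20 split
rng = np.random.default_rng(0)
order = rng.permutation(len(x))
tr, te = order[: int(0.8 * len(x))], order[int(0.8 * len(x)) :]
flat = x.reshape(len(x), -1)
tr_std, te_std, _, _ = standardize(flat[tr], flat[te])
model = DRSNRegressor(ModelConfig(training=TrainConfig(max_epochs=20, seed=0)))
train(model, tr_std.reshape(-1, 4, 712), y[tr])

# 5. evaluate on the held-out windows
pred = model.predict(te_std.reshape(-1, 4, 712))
report = compute_metrics(pred, y[te])
print(f"test MSE {report.mse:.1f}  Spearman {report.spearman:.3f}  "
      f"state accuracy {report.multiclass_acc:.2f}")
```

Output:

```
118 windows of shape (4, 712), PSI 16-95
  total_power_frontopolar        78.309
  total_power_left               36.392
  total_power_right              41.917
  rel_power_delta                 0.043
  rel_power_theta                 0.069
test MSE 89.3  Spearman 0.873  state accuracy 0.71
```

(Two subjects and 20 epochs is a demo; the benchmark below uses ten subjects
and reaches an MSE around 29.)

## Command-line pipeline

Each stage writes plain-text artifacts plus a `manifest.json` with the
configuration and its hash:

```bash
doaeeg simulate  --out data/raw --seed 3          # CSV per subject + labels
doaeeg preprocess --in data/raw --out data/clean  # segment, bandpass, clean
doaeeg extract-features --in data/clean --out data/features.csv
doaeeg train     --data data/clean --out runs/drsn --epochs 40
doaeeg evaluate  --data data/clean --features data/features.csv \
                 --cv subject --out runs/report
```

`doaeeg preprocess --no-eoa-removal` skips the (slow) artifact removal;
`doaeeg evaluate --ablate` adds the shrinkage-free ablated network.

## The model in brief

Each residual unit's branch ends in a channel-wise shrinkage module: per
channel, `x_avg = mean |x|`, a small FC net produces `α = sigmoid(z)`, and the
branch is soft-thresholded at `τ_c = α_c · x_avg_c` (so `0 ≤ τ_c ≤ x_avg_c`) —
small, noise-dominated activations are zeroed, large ones shrink by τ. Four
stacks (widths 8-8-16-16, stride-2 openings) feed a 1×1 convolution and
global average pooling into one value `v`, and the PSI prediction is
`p = 100/(1 + e^{-v})`. Training: Adam on MSE, batch 64, lr 0.005 × 0.9 every
20 epochs, L2 1e-4. See [docs/methods.md](docs/methods.md) for the full
description and the reasoning behind every default.

## Layout

| path | contents |
| --- | --- |
| `src/doaeeg/synth.py` | synthetic EEG generator + depth trajectories |
| `src/doaeeg/preprocess.py` | segmentation, FIR bandpass, WT–ICA–CEEMDAN cleaning |
| `src/doaeeg/emd.py` | EMD / CEEMDAN |
| `src/doaeeg/features.py` | multitaper PSD, band powers, SEF95, sample entropy |
| `src/doaeeg/nn.py` | NumPy layers with manual backprop |
| `src/doaeeg/drsn.py` | the DRSN-CW regressor and training loop |
| `src/doaeeg/baselines.py` | SVR / RF / MLP feature baselines |
| `src/doaeeg/evaluate.py` | metrics, folds, experiment driver |
| `src/doaeeg/io.py` | CSV/EDF reading, dataset and sample tables, manifests |
| `src/doaeeg/cli.py` | the `doaeeg` command |
| `docs/methods.md` | methods note: design choices and measured numbers |
| `scripts/acceptance.py` | recompute the headline quantities from scratch |
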