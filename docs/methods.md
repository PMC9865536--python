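# Methods

This note describes what `doaeeg` computes and why the defaults are what they
are. It is written to be self-contained: every constant that matters is stated
here together with the reasoning or measurement behind it.

## Problem setting

The package estimates a 0–100 depth-of-anesthesia index (PSI; 100 ≈ fully
awake) from 4-channel frontal EEG (electrodes L1, L2, R1, R2) sampled at
178.2 Hz. Estimation works on 4 s analysis windows — 712 samples per channel,
2848 values per flattened window — taken with 50 % overlap. Four anesthetized
states are defined from PSI: awake AW (80, 100], light LA (50, 80], normal
NA (25, 50] and deep DA [0, 25].

## Synthetic data generator (`doaeeg.synth`)

Clinical PSI-labeled recordings are proprietary, so the package ships a
generator with a known depth → spectrum → label structure:

* A latent depth trajectory `d(t) ∈ [0, 1]` follows an awake → induction →
  maintenance (with a brief deep dip) → emergence → recovery profile, built
  from jittered knots and a monotone piecewise-cubic interpolant. PSI is
  *defined* as `round(100·(1 − d))`, so a window's spectral content is, in
  principle, sufficient to recover its label. After segmentation, AW windows
  dominate and DA windows are rare, mimicking real peri-operative class
  imbalance.
* Each channel is a sum of band-limited Gaussian noises (delta, theta, alpha,
  beta, gamma) whose instantaneous variances follow depth-dependent weights:
  delta rises with depth, beta/gamma fall. Total RMS is 10 µV times a
  per-subject lognormal gain (log-SD 0.25), plus a 1/f background (2 µV RMS).
* Contamination adds: blink artifacts (Poisson 8/min by default, 300–500 ms
  biphasic pulses with the *same polarity* on all four frontal channels,
  topography [1.0, 0.8, 1.0, 0.8], peak 5× the clean-EEG RMS), 50 Hz line
  noise (3 µV), and sub-0.5 Hz drift (20 µV). The contaminated record keeps
  the clean record and each injected trace, so cleaning can be scored against
  ground truth.

Known limits: stationary within-band spectra (no burst suppression, no
spindles), independent channels apart from the shared blink source, and a
blink model that is smooth and biphasic. Conclusions about the relative
merits of models transfer only insofar as real EEG shares the
spectrum-encodes-depth property.

## Ocular-artifact removal (`doaeeg.preprocess`)

Windows are first bandpass filtered 1–51 Hz with a 401-tap linear-phase FIR
(Hamming), applied with reflect padding and delay compensation, so filtering
is time-aligned and (near) shape-preserving in the passband.

The cleaning chain has six steps:

1. **Wavelet stage** — each channel is split into additive multiresolution
   band components (db4, 4 levels). The components are full-length signals
   that sum exactly to the input; this, rather than raw downsampled DWT
   coefficient arrays, is used because at level 4 the approximation array
   holds only 51 samples — far too short for entropy estimates or ICA.
2. **ICA stage** — within each slow band (the two components below ~11 Hz,
   where blink energy lives), FastICA runs *across the four channels*. A
   blink is a single source seen by every frontal electrode with fixed
   polarity, so the cross-channel mixture is genuinely linear — exactly the
   model ICA assumes. Processing faster bands is configurable
   (`CleaningConfig.coeff_levels`) but off by default: blinks have <5 Hz
   content, and touching faster bands can only produce false positives.
3. **Classification** — a component is flagged as ocular only if (a) its
   sample entropy falls below `sampen_threshold` (blinks are large smooth
   pulses, hence highly regular), and (b) its mixing column is blink-like:
   same sign on every non-negligible channel and at least three channels
   loading above 0.3 of the peak. The topography check exists because
   entropy alone occasionally flags a genuine slow-EEG component (slow
   delta is also regular); removing one *increases* the error. On 36
   synthetic blink windows the check eliminated all such regressions at the
   5× operating point.
4. **CEEMDAN refinement** — the flagged components' contribution to each
   channel is decomposed by CEEMDAN, and only its low-entropy modes plus the
   slow residue are treated as artifact. This protects brain activity leaked
   into the flagged component.
5. **Subtraction** — the refined artifact estimate is subtracted.
6. **Reconstruction** — band components are summed back (exact, because the
   wavelet stage is additive). With nothing flagged, the whole chain is the
   identity to machine precision.

**Calibration of `sampen_threshold`.** On synthetic blink data the separation
between blink components and brain components is wide: blink ICs sit near
SampEn ≈ 0.05–0.15 while genuine band-limited EEG components sit above ≈ 0.5.
A threshold of 0.5 misclassifies genuine slow EEG as artifact; 0.3 flags all
blink components while leaving EEG components alone, and is the default.
Measured efficacy on 36 blink-bearing windows (mean RMSE reduction to the
clean truth): 27 % at 3× blink amplitude, 47 % at 5×, 68 % at 10×, with no
window made worse at 5× or 10×.

**Why cross-channel ICA (a deviation worth explaining).** An earlier variant
ran ICA per channel across that channel's CEEMDAN IMFs. It cannot work well
here: sifting distributes a blink *nonlinearly* across modes, so the IMF
stack does not follow ICA's linear mixing model, and the measured ceiling of
that design (even with an oracle classifier) was ~27 % RMSE reduction at 5×.
The blink is, however, exactly a linear shared source across channels, which
is why the ICA axis is cross-channel and CEEMDAN is used afterwards, to
refine what is subtracted.

CEEMDAN itself is the complete-ensemble variant: stage k adds the k-th IMF of
the *same* noise realizations to the current residue, and each extracted mode
is subtracted exactly, so completeness (`ΣIMF + residue = input`) holds by
construction. The default uses 50 ensemble trials (16 in the bulk-processing
`FAST_CLEANING` preset), 0.2×SD noise, and at most 8 modes.

## Features (`doaeeg.features`)

Fourteen features per window, in fixed order: absolute 1–51 Hz power of all
four channels, of the left pair, and of the right pair; five relative band
powers (delta 1–4, theta 4–8, alpha 8–14, beta 14–31, gamma 31–51 Hz) on the
all-channel average spectrum, normalized to sum to 1; the 95 % spectral edge
frequency of each hemisphere's average spectrum; and the sample entropy
SampEn(m=2, r=0.2·SD) of each channel. Spectra are multitaper estimates (4
DPSS tapers, time–halfbandwidth 2.5) — at 712 samples a single periodogram is
too erratic for stable band ratios. The sample entropy implementation is the
O(n²) definition, vectorized; the test suite pins it against a brute-force
template-counting oracle.

## Models

**DRSN-CW regressor (`doaeeg.drsn`, `doaeeg.nn`).** A 1-D deep residual
shrinkage network with channel-wise thresholds: four stacks of two
pre-activation residual units each (BN–ELU–Conv), widths 8-8-16-16, each
stack opening with a stride-2 unit. Every unit's branch output passes a
shrinkage module: per channel, `x_avg = mean |x|` (GAP of the magnitude map),
a two-layer FC net maps `x_avg` to logits `z`, `α = sigmoid(z)`, and the
soft threshold is `τ_c = α_c · x_avg_c` — guaranteeing `0 ≤ τ_c ≤ x_avg_c`.
Soft thresholding zeroes activations inside `[−τ, τ]` and shrinks the rest
toward zero by τ. A final BN–ELU, a 1×1 convolution collapsing 16 channels,
and global average pooling produce one value `v`; the prediction is
`p = 100/(1 + e^{−v})`, bounded in (0, 100). The ablated variant drops only
the shrinkage modules.

The network is implemented directly in NumPy with explicit backward passes
(there is no deep-learning framework in the dependency set). All layer
gradients are verified element-wise against central differences in the test
suite. Weights are float32 for speed; gradients are exact either way.

Training: Adam on MSE(p, PSI), batch 64, initial learning rate 0.005 decayed
×0.9 every 20 epochs, L2 10⁻⁴ on weight tensors (not biases/BN), inputs
standardized column-wise over the flattened 2848-vector using training-set
statistics only. Deterministic given the seed.

**Baselines (`doaeeg.baselines`).** On the standardized 14-feature vectors:
RBF-kernel SVR (C=1, ε=0.1), a 300-tree random forest, and a 14-64-16-1 MLP
with ReLU and Adam — all via scikit-learn.

## Evaluation (`doaeeg.evaluate`)

Regression error is mean squared PSI error plus Spearman rank correlation.
Classification metrics map predictions and truth to the four states and
compute one-vs-rest accuracy, sensitivity, precision and F1 per state,
macro-averaged (unweighted mean over states — appropriate given the strong
AW-heavy imbalance). Zero-denominator cells are defined as 0 and flagged
with a warning. Cross-validation is either random 5-fold or subject-grouped
5-fold (every sample of a subject stays in one fold).

## Benchmarks and problem sizes

All benchmark sizes are chosen so the full test suite runs in well under half
an hour on one desktop CPU core; they are package choices, not external
constraints.

* **Model comparison** — 10 subjects × 210 s at seed 11 → 1040 windows,
  bandpass-only preprocessing, random 5-fold CV, 30 DRSN epochs. Measured:
  DRSN MSE 29.1 vs ANN 30.2, RF 35.6, SVR 84.4; DRSN Spearman 0.93.
* **Shrinkage ablation** — the noise condition is the contaminated input
  itself: windows carrying 5× blinks, line noise and drift with no artifact
  removal. 6 subjects × 150 s per seed, 80/20 split, 40 epochs, three seeds.
  Measured: full MSE 37.7/28.9/33.7 vs ablated 39.1/40.1/59.3 (means 33.4 vs
  46.2). Two alternative designs were tried and rejected as unstable: very
  high contamination in train *and* test (direction flips between seeds) and
  heavy unseen noise injected only at test time (both models break down
  erratically under the distribution shift).
* **Artifact removal** — 36 blink-bearing windows from 3 subjects at 5×
  amplitude, 15 blinks/min, line noise disabled (it sits in the 1–51 Hz
  passband and is untouchable by a <11 Hz ocular chain, so it would only
  obscure the quantity being measured).

`scripts/acceptance.py` recomputes all of these from scratch for any seed.

## Limitations

* The generator's spectrum-encodes-depth assumption makes the task easier
  than clinical DoA estimation; absolute numbers do not transfer.
* The cleaning chain assumes blink-like (slow, same-polarity, broad) ocular
  artifacts; saccade spike potentials or asymmetric artifacts would need a
  different topography test.
* CEEMDAN and SampEn make bulk cleaning slow (~1 s per window with the fast
  preset); the benchmarks therefore use bandpass-only preprocessing, which
  also preserves the noise the ablation experiment needs.
* The NumPy network trains on CPU only; sizes beyond a few thousand windows
  per fold become impractical.
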