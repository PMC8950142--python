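# Methods

## Scope and model of the data

`erpdecode` studies single-trial decoding of face-evoked EEG under two
four-class paradigms, emotion × view (fear/neutral × upright/inverted) and
familiarity × view (famous/unfamous × upright/inverted). Because real
recordings of this kind are scarce and subject-specific, the package ships
a synthetic-data module that emulates the *structure* of such a study — a
cohort of control subjects plus one AD-like subject, balanced 4-class
events, 64-channel 10-10 montage at 250 Hz — and every downstream stage is
developed and tested against it.

## Simulator

Each class's evoked response is a sum of smooth idealized components; the
literature specifies component timings, not shapes, so we use the
conventional unimodal idealizations:

| component | shape | default | role |
|---|---|---|---|
| N170 | Gaussian, σ = 18 ms | −8 µV at 170 ms | face detection; latency +`inversion_delay_ms` (10 ms) for inverted views |
| N250 | Gaussian, σ = 25 ms | −4 µV at 250 ms | familiarity; famous classes add `n250_familiarity_delta_uv` (−2 µV) |
| emotion window | raised plateau, 20 ms cosine ramps | −1.5 µV over 310–1000 ms | fearful classes only |
| stimulus drive | plateau over 0–300 ms | +1 µV | screen-on drive during the stimulus |

Amplitudes are scaled by a per-subject `component_attenuation` and a
spatial region weight: posterior/temporal electrodes (O, PO, P, TP, T
prefixes) weight 1.0, central (CP, C) 0.5, frontal 0.1. Region matching is
case-sensitive on the letter part of a 10-10 label (`POz` → `PO`, `Fp1` →
`Fp`), so frontal lookalikes are never caught by posterior prefixes. The
64-label cap (61 standard scalp labels plus FT9/FT10/Iz, positions from
the standard MNE montage) retains exactly 35 channels under the
posterior/central prefix set with no bad channels.

Background noise is 1/f ("pink", exponent 1) noise obtained by spectral
shaping of white noise, normalized to unit RMS and scaled by
`noise_scale_uv` (default 6 µV RMS — low enough that, absent injected
artifacts, peak-to-peak amplitude stays below the 150 µV rejection bound
for nearly all epochs). With probability `artifact_rate` per trial a
200–400 µV Gaussian transient is injected on one channel. Continuous
recordings place the 1-s evoked template on a continuous pink-noise
carrier with 1.5 s between onsets (300 ms stimulus + ≥1 s pause), so
epochs never overlap. The AD profile uses attenuation 0.6, inversion delay
14 ms and artifact rate 0.08; the magnitudes of AD changes are a package
choice exposed in configuration, since no quantitative values are
established for the emulated patient.

Everything is a pure function of (configuration, seed): per-subject and
per-stage seeds spawn deterministically from a master `SeedSequence`.

**What the simulator is not.** It is not a biophysical forward model: no
dipole sources, no volume conduction, no ocular channels, no inter-subject
anatomical variability beyond the profile parameters, and the noise is
stationary. Tests passing on this generator show that the pipeline
recovers structure *of the kind the generator encodes* (latency shifts,
amplitude modulations, attenuation) at realistic SNR; they do not certify
performance on real recordings.

## Preprocessing

Order: band-pass → epoch → baseline → reject → select channels →
normalize.

- **Filter**: windowed-sinc FIR (Hamming), transition bandwidth 2 Hz
  (≈413 taps at 250 Hz), band 4–40 Hz, applied forward–backward
  (`filtfilt`) for exactly zero phase. A noiseless evoked recording keeps
  its N170 trough latency to within one sample after filtering.
- **Epochs**: half-open sample windows `[event + round(tmin·fs),
  event + round(tmax·fs))` with tmin = −0.2 s, tmax = 0.8 s → 250 samples;
  out-of-bounds events are skipped with a logged warning.
- **Baseline**: per trial and channel, the prestimulus mean is subtracted.
- **Rejection**: a trial is dropped iff its peak-to-peak range exceeds
  150 µV on *any* channel (the usual ERP convention); the decision is
  tested against an independent brute-force per-trial computation.
- **Channel selection**: longest-prefix, case-sensitive match of the
  label's letter part against {O, PO, P, TP, T, CP, C}; bad channels are
  dropped (never interpolated) before matching.
- **Normalization**: per-trial division by the trial's maximum absolute
  value (all-zero trials pass through unchanged), giving values in
  [−1, 1]. Per-trial scope keeps train/test statistically independent —
  no statistics leak across trials or subjects.

The channel count is carried as data-driven metadata throughout; fixtures
reproduce 35 channels, and nothing downstream assumes a fixed count.

## Classifier architectures

Four compact CNNs operate on single-trial planes `(1, C, T)`:

- **EEGNet**: temporal convolution (F1 = 8 kernels of length T/2, same
  padding, no bias) → BN → depthwise spatial convolution over all C
  electrodes (depth multiplier D = 2, max-norm 1) → BN → ELU → avg-pool
  (1,4) → dropout 0.5 → separable convolution (F2 = 16, length 16) → BN →
  ELU → avg-pool (1,8) → dropout 0.5 → dense softmax with max-norm 0.25.
- **DeepConvNet**: four conv blocks (25/25, 50, 100, 200 filters, temporal
  kernels of length TC = 10 at 250 Hz, all kernels max-norm 2, BN with
  ε = 1e−5, max-pool (1,2), dropout 0.5) → dense softmax with max-norm
  0.5. The block-1 dropout rate is not tabulated anywhere; we use 0.5 as
  in the other blocks. Convolutions keep their biases (BN follows, but the
  reference implementations keep them).
- **EEGNet-SSVEP**: EEGNet with a *full-length* temporal kernel (length
  T), F1 = F2 = 96, D = 1, and no max-norm bound on the dense layer.
- **EEGNet-SSVEP-reg**: the SSVEP variant with L1 and L2 penalties (0.001
  each) on the dense kernel only (not its bias).

Conventions where the sources are silent: no bias on any EEGNet-family
convolution (the original EEGNet convention); Glorot-uniform
initialization from an explicit seed; `T/2` and pooling use floor
semantics for odd T. Parameter counts are tested against closed-form
layer-by-layer hand counts for all four architectures.

### The NumPy layer engine

The networks are built on a small self-contained engine
(`erpdecode.nn`): stride-1 2-D convolutions (FFT path for long temporal
kernels, windowed-matmul path for short ones), depthwise spatial and
temporal convolutions, batch norm, ELU/LeakyReLU, average/max pooling,
inverted dropout, dense layers with optional max-norm constraints and
L1/L2 penalties, Adam, and an early-stopping fit loop that restores the
best validation state (weights *and* batch-norm running statistics). All
layer gradients are verified against finite-difference directional
derivatives, and the convolution primitives against `scipy.signal`
oracles. Entry layers skip the input-gradient computation, which roughly
halves the cost of the dominant first convolution.

## VAE augmentation

One convolutional VAE per class: encoder = 2 × (Conv 5×5, 16 filters,
LeakyReLU, BN) → flatten → dense heads for μ and log σ²; decoder mirrors
it (dense → reshape → convolutional reconstruction). Latent dimension 2,
Adam at 1e−4, batch 32, early stopping with patience 25 (defaults; scaled
down in tests). Training uses the reparameterization trick z = μ + σ·ε.

- **Likelihood**: the reconstruction term is squared error; for *training*
  it is summed over the (C × T) plane ("sum" reduction) so the KL term
  does not swamp the reconstruction gradient at [−1, 1] signal scale —
  this also matches the magnitude regime of per-class VAE losses reported
  for data of this shape. `vae_loss` exposes both reductions and returns
  (total, reconstruction, KL) with the closed-form KL
  ½ Σ(μ² + σ² − 1 − ln σ²).
- **Generation**: latent draws are N(0, 1) by default; a `uniform01`
  option draws from [0, 1) instead for compatibility with descriptions
  that feed uniform noise to the decoder. 1-D (time-only) kernels are
  available via `conv_rank=1`.
- **Splits**: per class 60/20/20 train/validation/test, floor for
  validation and test, remainder to train (952 trials → 572/190/190).
- Validation/test losses are evaluated at the posterior mean (ε = 0) so
  early stopping is deterministic.

A trained generator's sample mean correlates most with its own class's
real grand average — the class-retention property that makes the samples
usable for pretraining. Note an interaction with the band-pass: emotion
classes differ mainly by the slow 310–1000 ms plateau, which the 4 Hz
high-pass strongly attenuates, so emotion generators separate less sharply
than familiarity generators (whose N250 transient survives filtering).
Near-perfect synthetic separability is therefore demonstrated on the
familiarity paradigm.

## Training and evaluation design

- **Leave-subjects-out**: controls (minus the oldest) form the training
  pool; the oldest control and the AD subject are test-only. An audit on
  every fold raises if a test subject's trial enters training or
  validation.
- **Repeated two-fold CV**: 5 independent stratified re-partitions of the
  pooled training trials; the two folds alternate as train/validation
  (this resolves the ambiguity between a fixed 75/25 split and 2-fold CV
  in favor of trial-level folds, with subject-level hold-out kept
  separate). 10 runs total; per-run records and mean tables are exported.
- **Pretraining**: 500 synthetic epochs per class, shuffled 70/30; the
  held-out 30% serves as both validation monitor and test set (the
  published table reports both numbers on one holdout of 600). Published
  regime: 300 epochs, Adam, batch 128, lr 1e−5, patience 50.
- **Fine-tuning**: Adam, batch 64, lr 1e−3, early stopping on validation
  loss with patience 20, best state restored. When warm-starting from
  pretrained weights, batch-norm *running statistics are reset to (0, 1)*:
  they describe the synthetic distribution, whose per-feature variances
  are far smaller than noisy real epochs, and carrying them over saturates
  the logits and makes the transferred model confidently wrong. With the
  reset, warm starts are on average no worse at epoch 1 than random
  initialization.
- **Metrics**: accuracy (argmax, ties to the lowest class index), macro
  one-vs-rest AUC (the multiclass reduction is unspecified in the source
  tables; macro-OVR is the standard choice), per-class ROC curves, and
  confusion matrices with true classes as rows. The
  `confusion_view_split` summary partitions off-diagonal mass into
  cross-view vs within-view fractions.

## Desk-scale study conditions

The test suite and the acceptance script run the full design at reduced
size so that everything completes on one CPU:

- cohort of 4 subjects (2 training controls, the oldest control, one AD)
  × 96 trials, noise 3 µV RMS for the evaluation cohort ("moderate noise"
  relative to the −8 µV N170);
- posterior channel subset (prefixes O, PO, P → 17 channels) in
  training-heavy fixtures; the full 35-channel selection is exercised in
  preprocessing tests;
- scaled EEGNet-SSVEP-reg (F1 = F2 = 8) for cohort evaluations;
  fine-tuning 80 epochs with the published patience 20;
- VAE training 15–40 epochs with early stopping; classifier pretraining at
  lr 1e−4..3e−4 (instead of 1e−5) with 25–40 epochs.

Under these conditions the package reproduces the study's qualitative
findings: the inversion delay is recovered from grand averages within one
sample period; the trained decoder confuses same-view classes more than
opposite-view classes on the held-out control in ≥4 of 5 repeats; the
AD-like subject is decoded no better than the held-out control; permuting
training labels drives held-out accuracy to chance (25 ± 5 pp); and a
classifier trained on per-class VAE output separates the four familiarity
classes at ~100%.

## Known limitations

- The engine is CPU-bound NumPy; published-scale settings (96 temporal
  filters, 300–1000 epochs) are supported but slow, hence the scaled
  defaults in tests.
- The simulator's AD profile magnitudes are placeholders exposed as
  configuration, not fitted to patient data.
- Continuous recordings are written as MNE FIF (plus a TSV events sidecar
  and JSON manifest); EDF export would require an EDF writer dependency.
- Absolute VAE loss values depend on the reconstruction reduction and are
  not comparable across data shapes; only their ordering and convergence
  are meaningful.
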