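# Methods

## Scope and model

`eeg-augkit` implements a unified protocol for segment-wise EEG classification
with lightweight signal-domain augmentation:

1. three augmentation operators applied online to training draws,
2. three convolutional baselines (DeepConvNet-, ShallowConvNet- and
   EEGNet-style), and
3. stratified 10-fold cross-validation with Student-t confidence intervals and
   a hard leakage guard,

together with a synthetic generator that emulates the two study settings —
30-s two-channel sleep epochs at 100 Hz and 20-s two-channel iEEG segments at
512 Hz — so the whole pipeline runs with no external data.

## Augmentation operators

For a segment x(t) of length T:

* **Time shift (TS)** — x'(t) = x((t + Δt) mod T), a circular rotation. Δt is a
  signed integer drawn uniformly on ±⌊f·T⌋ with f = 0.30 by default. One Δt per
  segment, shared by all channels, preserving inter-channel phase relations.
  The rotation is exact: per-channel sample multisets, mean, std and energy are
  unchanged, and shift(−Δt) inverts shift(Δt) bit-exactly.
* **Amplitude scale (AS)** — x'(t) = α·x(t) with α ~ U(0.8, 1.2), one α per
  segment shared across channels (a global gain/impedance change).
* **Noise addition (NA)** — x'(t) = x(t) + ε(t), ε iid N(0, σ²) with
  σ = u·std(channel), a single u ~ U(0.01, 0.05) per segment applied per
  channel, because channels can differ in scale.

The online policy draws **one** method uniformly from the enabled set per
sample (no sequential composition) and applies it with probability
`apply_prob` (default 0.5), so raw and perturbed views of every segment both
appear across epochs. An alternative "append" mode streams every raw sample
plus one augmented copy per epoch; stochastic replacement is the default.
Randomness flows from one root seed through per-fold, per-purpose
(`shuffle`/`augment`/`dropout`) spawned generators, so runs are bit-reproducible
on CPU.

## Architectures

All models are built by a small in-package CPU neural-network toolkit
(`eeg_augkit.nn`: temporal/grouped/depthwise 1-D convolutions, batch norm,
max/average pooling, dropout, dense layers, softmax cross-entropy, Adam, full
backprop) operating on `(batch, channels, time)` float32 arrays. Classifier
input widths are always derived from the input geometry by a dry forward pass;
builders reject inputs too short for the pooling cascade and report the
minimum admissible length.

* **DeepConvNet** — five temporal-conv stages, widths [32, 32, 64, 64, 128],
  kernel 10, each + batch norm + ReLU + max-pool 4 (stride 4); then four dense
  layers (1024, 512, 256, 128) with batch norm and dropout 0.5, then a linear
  map to the classes. The five-stage width schedule, kernel length and pool
  stride are package choices where the architecture family leaves them open.
* **ShallowConvNet** — a spatial (kernel-1, across-electrode) convolution into
  40 filters, a depthwise temporal convolution (kernel 25), batch norm, ReLU,
  max-pool kernel 35 stride 7, one dense classifier. ReLU and max pooling are
  used (not the square/log + mean pooling of other shallow variants).
* **EEGNet-style** — a temporal filter bank (kernel 50, F1 = 8) shared across
  electrodes, a depthwise spatial filter spanning all electrodes (D = 2,
  F2 = 16), a depthwise-separable conv (kernel 16), ELU, average pooling 4 and
  8, dropout 0.25 in both blocks, and a dense head with one hidden layer of
  width 64. The hidden layer sizes the head near the commonly reported ~100 K
  parameter budget for this family and keeps the capacity ordering
  Shallow < EEGNet < Deep at the reference geometry (2 × 3000); a bare linear
  head would invert that ordering.

At the reference geometry (2 channels × 3000 samples, 2 classes) the counts
are 35,162 / 96,498 / 1,111,490 — verified in tests against independent
layer-arithmetic oracles.

## Cross-validation and aggregation

Stratified folds are built by shuffling each class's indices with the seeded
generator and dealing them round-robin, with the starting fold rotating per
class so remainders do not accumulate in early folds. This provably yields
disjoint, covering folds whose sizes and per-class counts differ by ≤ 1; an
independent brute-force recount validates every plan in the tests. Per-fold
accuracies M_i are summarised as mean M̄ (k-denominator), sample standard
deviation s (k−1 denominator), and the CI M̄ ± t_{(1+c)/2,k−1}·s/√k; for
k = 10 and c = 0.95, t = 2.262.

Each fold trains a freshly initialised model with Adam (lr 1e-3) and
cross-entropy — community defaults, surfaced in `TrainConfig` — up to
`max_epochs` with early stopping on validation loss (patience 20 by default)
and restoration of the best-epoch weights; the reported per-fold metric is the
restored model's validation accuracy. Augmentation applies only to training
draws; validation segments are never augmented. Two guards enforce this: a
hard error on any train/validation id overlap, and an instrumented log of
every augmented segment id that is checked against the validation fold.

## Synthetic generator

Every class signal is a unit-variance 1/f (pink, exponent 1) background plus
class-specific structure:

* **N3** — high-amplitude 0.5–2 Hz delta (gain 3× background), giving relative
  delta power ≈ 0.95; **Wake** — 8–12 Hz alpha (1.8×); **N1** — 4–7 Hz theta
  (1.5×); **N2** — theta (1.2×) plus Gaussian-windowed 12–14 Hz spindle bursts
  (0.5–1 s, Poisson rate 0.1/s); **REM** — low-amplitude mixed theta/beta
  (overall 0.7× scale).
* **Focal iEEG** — background plus broadband 4–30 Hz oscillation; focal
  segments add biphasic interictal spike-wave transients (~70 ms spike +
  ~200 ms wave, peak 6× background std, Poisson rate 1/s, random polarity and
  per-channel gain) and a slow (0.05–0.2 Hz) ±40% amplitude modulation.

Band-limited components are synthesised in the frequency domain (random phases
inside the band), so spectral contracts are structural rather than tuned. The
generator's obligations are class separability and those spectral contracts —
N3 delta fraction > 0.5, Wake alpha > delta, spindle-band power N2 > REM, focal
segments triggering a band-passed |z| > 5 detector more often than non-focal —
not physiological realism. It deliberately omits inter-subject variability,
artifacts, K-complexes and real spectra shape; passing tests therefore
demonstrate protocol correctness and trainability, not real-data accuracy.
The default composition mirrors the balanced study subset (8000 N3 + 2000
each of Wake/REM/N1/N2 = 16,000 epochs).

## Preprocessing

Sleep recordings: 0.1–50 Hz band-pass (4th-order Butterworth, applied
forward–backward for zero phase; order and band configurable), segmentation
into half-open 30-s windows along the hypnogram with 0-based sample indexing
(partial or non-finite epochs dropped and logged), then per-channel z-scoring
with the sample (k−1) std; a flat channel is treated as a recording failure
and raises. iEEG segments receive z-scoring only. The two-column ASCII dialect
round-trips bit-exactly; the included 16-bit EDF writer produces fixtures that
round-trip within quantisation of the physical range.

## Scaled-down experiments and their problem sizes

Desk-scale sizes were chosen so the full suite runs in minutes on one CPU:

* **Trainability smoke** — 200 segments, 2 × 1500 samples, amplitude-offset
  classes; every architecture must reach ≥ 95% training accuracy within 30
  epochs (all three typically do so within 4).
* **Augmentation robustness** — 400 five-second sleep epochs (200 N3, 50 each
  of the other stages), binary N3-vs-rest, EEGNet spec, 10-fold CV, validation
  folds perturbed by a random circular shift (≤ 20% of the window) and gain
  jitter (±15%); raw vs raw+TS compared over 5 root seeds. In a 10-seed pilot
  both conditions scored 1.0000 on every seed: the synthetic N3 signature is
  strongly separable and largely shift/gain-invariant, so the experiment
  demonstrates *non-inferiority* of augmented training under distribution
  shift at this scale rather than a strict gain. The acceptance criterion is
  accordingly mean(raw+TS) ≥ mean(raw).
* **Noise-scale stability** — training with NA ranges 0.5–3% vs 2–8% of the
  signal std (2 seeds, k = 5) must agree within 5 accuracy points.

## Numerical choices and limitations

* float32 parameters and activations; forward passes in evaluation mode are
  deterministic; training is bit-reproducible per seed on CPU.
* Batch-norm uses momentum 0.1 running statistics for evaluation; eps 1e-5.
* 'same' temporal padding keeps kernel length from truncating short inputs
  (even kernels shorten the map by one step, accounted for in geometry checks).
* Cross-entropy is computed in float64 with a 1e-12 probability floor.
* Subject-wise/patient-wise splitting is out of scope: folds stratify over
  segments, as in the segment-wise protocol the package implements; metrics
  beyond accuracy (sensitivity/specificity) are not computed.
* The full-scale published accuracies require the two external corpora and
  GPU-scale training; this package reproduces the protocol and its
  self-contained quantities, not those tables.
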