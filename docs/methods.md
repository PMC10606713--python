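# Methods

## Problem and pipeline

Sleep EEG microstructure alternates between activation (A) and background
(B) phases, scored per second.  `capnet` treats the per-second decision as
image classification: each second, extended by symmetric context to a
W-second window at 32 Hz, is mapped to a 2-D time-frequency image and
classified by a CNN.  The label of a window is that of its central second
only — context informs the decision but never the target.

## Sampling and segmentation

* **32 Hz analysis rate.** CAP-relevant content lives below ~16 Hz (A1 at
  0.5–4 Hz, A3 at 8–12 Hz), so records of any input rate ≥ 32 Hz are
  polyphase-resampled to 32 Hz (scipy `resample_poly`, linear-phase Kaiser
  low-pass).  Resampling is done once per record rather than per segment —
  mathematically equivalent away from edges and far cheaper.  Measured on
  tones: passband (1–12 Hz) flat within 0.5 dB, 30 Hz content attenuated
  by > 40 dB (steady state).
* **Seconds are 0-based, half-open** `[t, t+1)` → samples `32t … 32t+31`.
* **Block splits.** The recording is cut into non-overlapping 300 s
  blocks: within each block the first 240 s are training, the next 30 s
  validation, the last 30 s test, so all three sets sample the whole
  night.  A trailing partial block follows the same offsets.
* **Edge trimming.** A context window that straddles a split boundary
  would leak test signal into training; every segment whose W seconds are
  not wholly inside its own split is dropped.  When time-shift
  augmentation will widen training windows by a margin, trimming is done
  at the widened width.
* **Balancing.** B seconds dominate real CAP annotations roughly 5:1.
  Per recording *and per split*, B segments are randomly removed (seeded,
  without replacement) until B equals A; A segments are never dropped.
  The test split keeps its natural composition — balanced evaluation
  subsamples at scoring time, so one prepared dataset serves both
  evaluation modes.  Trimming precedes balancing.

## Time-frequency representations

All three transforms output rows = frequency ascending over [0, 16] Hz and
one column per sample, on the analytic signal where applicable.

* **Spectrogram**: Hann window of 20% of the segment length (forced odd),
  hop of one sample, squared magnitude; edge frames are zero-padded.
  Fed linearly — no dB compression — because the σ̄ normalization (below)
  is built around preserved energy ratios.
* **WVD**: per time index the lag kernel `r_n[m] = z[n+m] z*[n−m]` over
  the largest symmetric in-segment lag range (no padding), DFT over m.
  Because m steps the physical lag by two samples, `n_freq` bins cover
  exactly [0, 16) Hz at 32 Hz.  Output scaled by `1/n_freq` so the column
  sum equals `|z[n]|²` exactly and the image total equals the
  analytic-signal energy.  `n_freq` defaults to the next power of two ≥
  the segment length.
* **SPWVD**: separable kernel — lag taper h, circular time smoothing g —
  algebraically identical to multiplying the ambiguity function by
  `Φ(ν,τ) = G(ν)·h(τ)` (verified to 1e-14 against a brute-force
  ambiguity-domain evaluation).  Default tapers are Kaiser (β = 20), g of
  length ≈ N/10 and h of length ≈ N/4 (nearest odd), unit peak.  With g a
  delta and h all-ones the SPWVD collapses to the WVD bit-for-bit.  On a
  4 + 10 Hz two-tone test the 7 Hz cross-term band retains < 25% of its
  WVD energy while the tone bands keep > 75%.  The exact kernel of any
  particular external implementation is unknowable; the ambiguity-route
  identity pins the mathematics, and the taper shapes/lengths are config
  knobs the ablation harness can sweep.

## Normalization and augmentation

Per-image standardization would equalize A and B image energies — the very
feature that separates them.  Instead each image is centered and divided
by σ̄, the mean per-image pixel standard deviation of the *training* set:
std ratios between images are preserved, and when all per-image stds are
equal the scheme coincides with classic standardization.  σ is computed
over image pixels (an equivalent per-1-D-segment variant would differ only
by the transform's energy mapping; pixels are what the network sees).

Augmentations (per batch, on normalized images, all driven by one
generator): AWGN with std drawn uniformly from (0, 0.05) in normalized
units; Gaussian blur with probability 0.5, σ ∈ (0.5, 1.5) px, kernel
truncated at 4σ; SpecAugment-style masks — one time band up to 5% of the
width and one frequency band up to 3% of the height, filled with the image
mean; time crop-and-resize up to 10% of columns (the "stretch events"
augmentation acts on the time axis; stretching frequency would corrupt the
spectral signature that distinguishes the phases).  Random time-shifts are
horizontal crops of windows pre-extended by ±1 s, a dataset-preparation
option rather than an image op, since they need extra signal context.

## Models and training

* **resnet18_gray_binary** — the standard 2-2-2-2 basic-block ResNet18
  with a single-channel 7×7 stem and a 2-logit head, randomly initialized
  (He for convs); global average pooling makes it input-size agnostic
  (minimum 32×32).  11.17 M parameters.  This is the reference
  architecture; training it to convergence is a GPU-scale job.
* **small_cnn** — three conv-BN-ReLU blocks (8/16/32 channels, overall
  /8 downsampling), a center+context pooling head (global average
  concatenated with the average over the central fifth of the time axis —
  the labeled second, for a 5 s window), and a linear classifier.  Pure
  global pooling cannot localize the window center, and with it wide
  windows *hurt* whenever A events are about window-sized; the center
  branch restores the positional signal the central-second labeling rule
  relies on.  Desk-scale only; not part of the reference recipe.
* **Training** — cross-entropy, SGD with momentum; defaults are the
  reference recipe (batch 256, lr 0.001, momentum 0.9, 40 epochs, no
  dropout, no weight decay, no schedule).  The checkpoint with the best
  validation accuracy is kept (earliest epoch on ties).  The stack is pure
  NumPy with explicit backward passes, so identical seeds give
  bit-identical histories.  Ties in the class decision go to B, the
  background.  The scaled-down harness runs explicitly override to batch
  16 / lr 0.05 / 5 epochs: with batch 256 a ~1000-image balanced training
  set yields only four SGD steps per epoch, too few to constitute a
  training run.  The override was selected on *validation* accuracy
  stability across training seeds; smaller batches (more SGD steps within
  the fixed 5 epochs) were the decisive factor.

## Evaluation

A is the positive class: ACC = (tp+tn)/total, PRE = tp/(tp+fp),
REC = tp/(tp+fn), SPE = tn/(tn+fp), F1 = 2tp/(2tp+fp+fn).  Zero
denominators yield NaN with a warning, never silently 0.  Per-subtype TPR
is the share of a true subtype's instances predicted as A at all (the
classifier is binary); for B it is the correctly-kept-as-B share.
Weighted by column counts, the A-subtype TPRs reproduce REC exactly.
Percentages are rendered at one decimal; full precision is kept
internally.  Balanced evaluation subsamples B test seconds (seeded) to the
A count; unbalanced keeps the natural ratio; the decision rule is
identical in both modes.

## Synthetic generator

The generator produces what the classifier is trained to exploit and
nothing more: unit-RMS pink noise (PSD ∝ 1/f) band-limited to 0.3–16 Hz as
the B-phase background, with A events added on top as band-limited noise
bursts — A1: 0.5–4 Hz at 3.0× background RMS; A3: 8–12 Hz at 0.7×; A2: a
2.0× slow plus 0.7× fast component.  The gains follow the qualitative
description of the phases (A1 strong and slow, A3 faster and weaker) and
are calibration knobs, not physiological claims.  Events last 2–10 s
(drawn per event), are aligned to whole seconds, never overlap, and are
separated by ≥ 2 s of background so every event is a distinct labeled run;
onsets/offsets get a 0.25 s cosine ramp.  The default A fraction used in
the scaled-down study is 0.2, giving the strong B dominance of real
scorings.

What it does **not** model: sleep macrostructure (REM/NREM cycling),
artifacts (EMG, eye movement, electrode pops), inter-subject variability,
sub-second event boundaries, or any channel/montage effects.  Passing
tests on this generator therefore demonstrate that the pipeline's
machinery is correct and that the classifier recovers planted
spectral/energy structure — not that real-EEG accuracy figures are
reproduced.  Reaching the published accuracy on real data requires the
public CAP database and ResNet18-scale training, both outside the
desk-scale harness.

## Problem sizes in the shipped tests

The scaled-down study uses one 3000 s synthetic record (≈ 600 A seconds),
5 s windows, SPWVD images on a 64-bin frequency grid (64×160; the
transform's default next-power-of-two grid oversamples frequency for this
purpose and quadruples compute), and the small CNN for 5 epochs; the
context ablation compares 5 s and 1 s windows over three training seeds on
the same record.  These sizes give stable, seed-robust results while
keeping the whole suite CPU-friendly.

## Known limitations

* The WVD/SPWVD images of a pure tone spread over a few bins near segment
  edges (truncated lag windows); concentration tests therefore measure
  squared-energy fractions over ±3 bins on interior columns.
* The EDF writer is a minimal 16-bit encoder (1 s records, symmetric
  physical range) intended for fixtures and synthetic exports, not a
  general-purpose clinical EDF producer.
* Scoring-guideline post-processing of predicted A/B sequences (minimum
  event durations, CAP-cycle rules) is deliberately out of scope.
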