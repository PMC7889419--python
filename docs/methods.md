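# Methods

## Problem and pipeline

`scindex` implements a machine-learned analgesic index for conscious
patients: given a single-channel photoplethysmogram (PPG), it produces a
0–100 "likelihood of pain" value every 10 seconds. The pipeline has four
stages.

1. **Conditioning.** The PPG (nominally 300 Hz, arbitrary amplitude
   units) is bandpass filtered to 0.5–10 Hz with a linear-phase FIR
   filter, smoothed with a 30-tap moving average, and z-scored over the
   full 5-minute analysis segment (mean 0, population SD 1). Because the
   filters are linear and the z-score removes offset and gain, the
   pipeline is invariant to positive affine rescaling of the raw signal,
   as it must be for an arbitrary-unit waveform.
2. **Spectrogram patches.** Each non-overlapping 10-s window is turned
   into a short-time Fourier transform image: 6.3-s Hamming-windowed
   segments every 0.03 s (1890 samples, hop 9), zero-padded FFT of
   3690 points, magnitude of the bins spanning 0–10 Hz. The geometry
   gives exactly 124 time frames and 124 frequency bins, i.e. a
   124 × 124 patch; a 5-minute recording yields 30 patches.
3. **CNN scorer.** A small convolutional network maps a patch to two
   softmax probabilities (no-pain, pain). Three Conv–Maxpool stages with
   32, 64 and 128 filters (2 × 2 kernels, stride 1, size-preserving
   padding; 2 × 2 stride-2 max pooling; batch normalisation + ReLU per
   stage) reduce the spatial size 124 → 62 → 31 → 15, giving a
   15 × 15 × 128 = 28,800-wide flattened feature vector, followed by two
   fully connected ReLU layers (256, 64) with dropout 0.5 and a 2-node
   softmax output. Training minimises cross-entropy with Adam and
   early-stops on validation loss; dropout and batch statistics are
   training-only, so inference is deterministic. The **spectrogram–CNN
   index** of a patch is 100 × the pain-node probability; a recording is
   summarised by the mean index over its patches.
4. **Evaluation.** Subjects — never patches — are partitioned into five
   folds (with 100 subjects: 20 test / 73 train / 7 validation per
   fold), so no individual contributes data to more than one role.
   Performance is reported as ROC AUC, the best-fit cutoff (maximum
   sensitivity + specificity under the rule *index ≥ cutoff ⇒ pain*,
   ties to the lowest threshold), sensitivity, specificity and balanced
   accuracy = (sensitivity + specificity)/2. A permutation test
   re-evaluates balanced accuracy under randomly shuffled test labels to
   locate chance level.

## Synthetic cohort generator

No public PPG pain dataset accompanies this problem, so the package
ships a generator that emulates the paired study design: per subject,
one 5-minute baseline recording (VAS 0, label 0) and one post-operative
recording (VAS ≥ 1, label 1) at 300 Hz. Labels follow the VAS rule
exactly: pain iff VAS > 0.

Each recording is a sum of per-beat pulse templates — a systolic
Gaussian lobe (centre 0.18 s, width 0.08 s) plus a smaller dicrotic lobe
(0.35 amplitude, centre 0.42 s, width 0.10 s) — scaled by the
condition's pulse amplitude, amplitude-modulated by respiration
(default 0.25 Hz, depth 0.2) and embedded in white Gaussian noise
(SD 0.05). The template shape was chosen once so that the spectral
fundamental dominates its harmonics across 50–120 beats/min, keeping
heart rate the dominant feature in the 0–10 Hz band the spectrogram
sees. Beat onsets come from i.i.d. truncated-normal inter-beat intervals
(mean 60/HR s, SD = SDNN/1000 s, floor 0.25 s).

The pain condition applies a sympathetic-activation signature to the
subject's own baseline physiology: +15 beats/min heart rate, −40% SDNN
(50 → 30 ms), −30% pulse amplitude (1.0 → 0.7). These magnitudes are
configurable model choices in the direction reported for nociceptive
arousal, not estimates of any patient population. Between-subject
variation is a baseline heart rate drawn once per subject
(SD 8 beats/min) and shared by both conditions, making the pain contrast
within-subject as in the paired design. Setting the pain parameters
equal to the no-pain parameters produces a *null cohort* in which no
statistic should separate the classes.

What the generator does **not** emulate: long-range heart-rate
variability correlations (intervals are i.i.d.), motion artifacts,
arrhythmia, baseline wander, sensor nonlinearities, and any pulse
morphology change with pain other than amplitude. Passing tests
therefore demonstrate that the pipeline recovers a heart-rate/HRV/
amplitude signature from realistic spectrograms — not that the index
works on real patients.

## Numerical choices

- **FIR design.** Hamming windowed-sinc, 901 taps at 300 Hz, applied
  forward–backward (zero phase, so patch timing is unshifted).
  Measured response: gain ≈ 1.007 at 2 Hz, ≈ 3 × 10⁻⁴ at DC, < −80 dB
  at 50 Hz. A 0.5-Hz lower edge needs a transition band of roughly
  1 Hz, which a ~300-tap design at this rate cannot provide; any design
  meeting the same passband/stopband contracts is interchangeable.
- **Filter order.** Bandpass first, then moving average (their cascade
  is commutative in exact arithmetic; the order fixes edge handling).
- **Moving average.** Centred, reflective edges; a causal variant is
  available (`ma_centered=False`) for streaming-style use.
- **z-score.** Population SD (divide by N), over the full recording
  rather than per patch, since normalisation exists to remove
  inter-measurement gain differences.
- **Spectrogram scale.** FFT length 3690 makes the bin spacing
  300/3690 ≈ 0.0813 Hz so that bins 0–123 tile 0–10 Hz exactly; the
  stated patch size is reproduced rather than resized. Magnitudes are
  compressed as log(1 + |S|) and each patch min–max scaled to [0, 1]
  before the network (both configurable); compressive scaling keeps the
  dynamic range of harmonics manageable for training.
- **Geometry validation.** Any parameter set whose frame or bin count
  differs from the configured 124 × 124 is rejected at construction,
  never silently cropped or interpolated.
- **CNN engine.** The conv/batch-norm/pool/dense/dropout/Adam stack is
  implemented directly on numpy (im2col convolutions evaluated as BLAS
  matrix products, NHWC float32), gradient-checked against central
  finite differences. 'Same' padding for the even 2 × 2 kernel puts the
  extra row/column at bottom/right; it is forced because only
  size-preserving convolutions reproduce the 124 → 62 → 31 → 15 trace
  (valid convolutions would give 14 at stage 3). Max-pool ties share
  gradient equally so the backward pass is an exact adjoint. The
  classifier head is initialised at small scale so initial logits are
  near zero and the first cross-entropy starts near ln 2.
- **Training defaults.** Adam lr 10⁻³, batch 32, dropout 0.5, early
  stopping on validation loss (patience 5, max 50 epochs at full scale);
  the parameter state of the best validation epoch is returned. Seeds
  control initialisation, shuffling and dropout, so runs are exactly
  reproducible.
- **Folds.** The validation set takes the largest integer strictly
  below `val_fraction × n_dev` subjects (at least 1), which yields the
  published 20/73/7 split for 100 subjects at `val_fraction = 0.1`.
- **Cutoff rule.** `index ≥ cutoff ⇒ pain`; candidate thresholds are the
  observed scores plus +∞; ties resolve to the lowest maximiser.
- **Permutation null.** Default holds the best-fit cutoff of the
  unpermuted data fixed while labels are shuffled, centring the null at
  50% by exchangeability. Re-optimising the cutoff per permutation
  (`cutoff_rule="refit"`) is also provided but is biased: the maximised
  sensitivity + specificity can never fall below 100%, so every
  permuted balanced accuracy is ≥ 50% and the mean sits above chance; a
  chance-level reference that can dip below 50% requires the fixed rule.
- **AUC confidence intervals.** Percentile bootstrap resampling
  subjects (the independent unit), optional via `n_boot`.

## Desk-scale study sizes

The test suite and the acceptance script run the full pipeline at sizes
chosen to exercise every stage on a single CPU:

- learning checks: a 40-subject separable cohort, five seeded runs,
  each on its own subject-disjoint split (26 train / 6 validation /
  8 test), 6 training patches per recording, up to 6 epochs with
  early stopping (patience 3), long enough to fit the training set;
- null-cohort check: 60 subjects, 8 training subjects, 50 test
  subjects, 2 epochs;
- permutation reference: a 100-subject cohort, fold 0 of the 5-fold
  split (73/7/20), 5 training patches per recording, 2 epochs, 100
  permutations of the 1,200 held-out test-patch scores.

Because synthetic subjects are exchangeable, the validation and test
AUCs of a run differ only through the subject draw and the early-stop
selection on validation loss; the train ≥ validation ≥ test ordering
seen in patient data (where validation also guided model selection) is
correspondingly weaker here and is assessed over the majority of the
seeded runs.

## Known limitations

- The generator's effect sizes are stand-ins; nothing here estimates
  how real pain changes a PPG.
- Patch-level ROC statistics treat the 30 patches of a recording as
  repeated measures of one subject; intervals that ignore this are
  anti-conservative, which is why bootstrap CIs resample subjects.
- The numpy CNN engine is CPU-bound and single-threaded through BLAS;
  it is sized for desk-scale cohorts, not large clinical datasets.
- WFDB ingestion is not provided; recordings travel as delimited text.
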