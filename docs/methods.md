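# Methods

## Problem

Auscultation classifies heart sounds (phonocardiograms, PCG) into normal
(N) and four valvular disorders — aortic stenosis (AS), mitral
regurgitation (MR), mitral stenosis (MS), mitral valve prolapse (MVP) —
from the timing and frequency content of the S1/S2 transients and of
murmurs between them. `pcgkit` implements a full pipeline from mono WAV
recordings to a cross-validated deep classifier: signal conditioning,
background-deformation augmentation, time-frequency imaging, and a
convolutional vision transformer with attentional fusion of texture (LBP)
and convolutional features.

## Signal conditioning

Recordings are conditioned in a fixed order:

1. **Acquisition band-pass** — 3rd-order Butterworth, 25–900 Hz, applied
   at the native sampling rate (nominally 8 kHz) to strip sensor and
   out-of-band noise. Skipped when the input already arrives at the
   analysis rate.
2. **Decimation to 2000 Hz** — polyphase, anti-aliased
   (`scipy.signal.resample_poly`); output length is `ceil(N/4)` from 8 kHz.
3. **Analysis band-pass** — 3rd-order Butterworth, 15–150 Hz, applied
   forward–backward (`filtfilt`). Zero-phase filtering preserves S1/S2
   timing exactly; the effective magnitude response is the single-pass
   response squared, so stop-band attenuation doubles in dB.
4. **Optional wavelet denoise** (off by default) — 5-level `db4`
   decomposition, soft threshold at the universal level
   `sigma*sqrt(2 log N)` with `sigma` from the MAD of the finest detail
   band. Provided as an alternative noise-suppression path; the
   Butterworth stages are the primary mechanism.
5. **Peak normalization** — max |amplitude| = 1; an all-zero signal is
   returned unchanged with a warning.
6. **Fixed length 2312 samples** (1.156 s at 2 kHz, the shortest
   recording in the reference database, `ceil(1.1556 * 2000)`). Longer
   recordings keep their head (the first cardiac cycle); shorter ones are
   zero-padded at the tail. Head truncation is deterministic and keeps the
   first S1.

## Augmentation

A training copy is `x + delta * b` with `delta ~ Uniform(0,1)` drawn
strictly inside the open interval (endpoints re-drawn) and `b` an
equal-length unit-RMS background. The default background is Gaussian noise
zero-phase band-limited to 15–150 Hz; a "recording-mix" mode instead uses
a different same-class recording, length-matched. Augmentation never
touches test folds. Two roster modes exist because the published protocol
augments *all* originals into the training roster (10-fold over 2000
originals: 1800 train originals + 2000 augmented = 3800), which leaks
held-out signal content into training; the default `leakage_free` mode
augments training originals only (1800 + 1800 = 3600) and the
`paper_faithful` mode reproduces the 3800-record arithmetic.

## Time-frequency imaging

* **STFT power spectrogram**: `|STFT|^2` with a periodic Hann window of
  256 samples (128 ms at 2 kHz), hop 64, 512-point FFT. No window-gain
  scaling, so values equal the squared magnitude of the windowed frame
  DFT exactly.
* **CWT scalogram**: analytic Morlet (angular center frequency 6), 12
  voices per octave, pseudo-frequencies log-spaced over 10–500 Hz. A
  constant-Q representation: frequency resolution is proportional to
  frequency.

Either matrix renders to an RGB image: dB scale (`10 log10`, floored at
−80 dB relative to the matrix peak), per-image min–max to [0, 1], a
256-entry colormap lookup table shipped as a package fixture (so rendering
is bit-identical across platforms), then align-corners bilinear resizing
to the configured square size with low frequencies at the bottom row.
Resizing to the native size is exactly the identity.

**Which representation to train on.** The CLI defaults to the scalogram
for rendering, reflecting its constant-Q advantages for transients. For
*classification* we measured the opposite at desk scale: after the
15–150 Hz analysis filter, the murmur band (≥150 Hz) survives only as an
attenuated leak just above the filter edge; on the scalogram's
log-frequency axis that leak occupies roughly two of 64 image rows,
whereas on the spectrogram's linear axis it spans half the image height.
A linear probe on rendered 64 px images separates the murmur-envelope
classes (AS vs MR) at chance-adjacent levels from scalograms but
perfectly from spectrograms. The end-to-end evaluation therefore trains
on STFT images; both paths are first-class and selectable.

## The classifier

* **Backbone**: 17 convolutions (3x3, stride/pad 1, BatchNorm + ReLU) in
  six stages of widths 32→1024 (full profile), with a 2x2/stride-2 max
  pool after each of the first five stages; width doubles after each
  pool. 224x224 input → 7x7x1024 feature map.
* **LBP branch**: the grayscale input's radius-1/8-neighbor local binary
  pattern code map (codes/255), through a small stem of five conv+pool
  blocks and a final conv, ending at the backbone's spatial size and
  width. The LBP variant is pinned (>= comparison, clockwise bit order
  from the top-left, replicate padding) for exact reproducibility.
* **Attentional selective fusion**: `U = WL*LBP + WC*CNN` (1x1
  convolutions); gate `G = sigmoid(global(U) + local(U))` where the
  global context is the spatial mean passed through a
  reduce-by-4/ReLU/expand bottleneck and the local context a per-pixel
  1x1 convolution; output `G.*(WL*LBP) + (1-G).*(WC*CNN)`.
* **Tokenizer**: the fused map is split along its width into column
  strips (7 at 224 input), each flattened and linearly projected to the
  1024-d embedding; learned per-token position embeddings are added. For
  384-input fine-tuning the embeddings are linearly interpolated 7→12.
* **Encoder**: pre-norm transformer blocks (default depth 1) of 8-head
  self-attention and a 2048-wide ReLU feed-forward, each residual.
* **Head**: mean-pool over tokens → 2048-wide ReLU layer → linear →
  softmax. Ties in argmax break toward the lowest class index.

The full profile carries ~68.7 M parameters. The published description
left stage depths and widths open; ours is the narrowest reading
consistent with "17 convolutions, 5 pools, width doubling, 1024-d
embedding", and the parameter total is reported but not asserted against
any external figure. A desk-scale `test_profile` (64 px input, widths
8→256, 256-d embedding) trains on one CPU.

The network, including reverse-mode differentiation of every layer, is
implemented directly on numpy (`pcgkit.nn.autodiff`); gradients are
validated against central finite differences along random directions.
Training uses SGD with momentum 0.9 (cross-entropy loss), cosine
learning-rate decay from 0.01, batch 16, and is fully seeded; BatchNorm
uses batch statistics in training and running averages in evaluation.

## Synthetic data

The generator emulates what the pipeline needs to be testable end to end
without the deposited recordings: 1.2 s cycles at 60–100 bpm sampled at
2 kHz, S1/S2 as damped tone bursts (50–120 / 60–150 Hz, systole fixed at
35% of the cycle), class murmurs as band-noise shaped by textbook
envelopes — AS: mid-systolic crescendo–decrescendo (150–400 Hz); MR: flat
holosystolic; MS: mid-diastolic 40–100 Hz rumble; MVP: ~5 ms mid-systolic
click plus late-systolic ramp; N: none — white noise at 20 dB SNR, peak
normalization. Classes are constructed to be spectrally/temporally
separable (a two-feature band-energy rule distinguishes N/AS/MS at >95%);
the generator does **not** model respiration, sensor motion, subject
variability, or realistic murmur spectra, so passing tests demonstrate
pipeline correctness and model capacity, not clinical performance.

## Evaluation

Stratified k-fold (default 10; per-class counts equal up to one,
`StratifiedKFold` with shuffling, seeded). Per-class one-vs-rest counts
give ACC/SE/SP/PR on the 0–100 scale and F1 as the harmonic mean of PR
and SE; macro values are unweighted class means; zero denominators yield
0 with an explicit flag. One-vs-rest ROC curves are summarized by
trapezoid-rule AUC; an undefined AUC (single-class fold) is NaN and
excluded from the macro mean.

The desk-scale end-to-end check uses 50 synthetic recordings per class,
2-fold CV, the `test_profile` model on 64 px STFT images, one augmented
copy per training original, and 25 training epochs — sized so the whole
run fits in minutes on one CPU while leaving headroom above the 90%
mean-accuracy bar it is expected to clear.

## Numerical choices and edge cases

* float32 parameters/activations; float64 signal processing.
* dB floor −80 dB prevents `log(0)`; an all-zero matrix renders as a
  uniform image at colormap entry 0.
* Max-pool gradient ties route to the first maximum in the window.
* WAV quantization: write scales by 2^15 with clipping of the single
  overflowing code, so a write/read round trip errs at most 1/32768.
* Upsampling is unsupported (the method only ever decimates).
* Recordings shorter than ~3x the filter order cannot be zero-phase
  filtered and raise a clear error.

## Known limitations

* The synthetic murmur classes AS and MR differ only in systolic envelope
  shape; after the 15–150 Hz analysis stage their separability rests on
  the attenuated band-edge leak (see the representation note above).
* BatchNorm requires at least two samples per training batch; trailing
  singleton batches are skipped.
* The full-profile network trains impractically slowly on one CPU; it is
  provided for architectural fidelity and summary/inspection, while the
  test profile is the practical desk-scale configuration.
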