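# Methods

This note documents the models and procedures implemented in `herdcall`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Level metric and event capture

A digital clip has no absolute sound-pressure level, so the toolkit defines
its level as `20·log10(max|amplitude|) + calibration_offset` with a default
offset of 60 dB: a full-scale clip sits exactly at the 60 dB capture
threshold, which keeps the conventional "record above 60 dB" rule
meaningful on synthetic data. The trigger scans 100 ms windows with a 50 ms
hop — short relative to the 5 s record length, so trigger-time quantization
is negligible — and a trigger during an active recording is absorbed by it,
making events non-overlapping by construction. Cross-sensor deduplication
buckets trigger times by `floor(t / coincidence_window)` with a 1 s default
window and keeps the loudest event per (zone, bucket); bucketing makes the
operation idempotent and gives an exact survivor count, at the cost of not
merging events that straddle a bucket boundary.

The working sample rate defaults to 16 kHz; every operation is
parameterized by rate.

## Spectral gating

The short-time Fourier transform uses non-centered frames (column l covers
samples `[lH, lH + window)`), FFT size 2048, window length 2048, hop 256,
periodic Hann taper. A 5 s clip at 16 kHz therefore yields
`1 + (80000 − 2048) // 256 = 305` frames.

Noise statistics are taken on dB magnitudes — matching how noise floors
are usually displayed and compressed — rather than on linear power, whose
dynamic range would let a few loud cells dominate the mean. The gate
threshold is `mean + n_std · std` per frequency bin with `n_std = 1.5`, a
common spectral-gating default; the multiplier is configurable. When no
dedicated noise recording is available, the quietest 0.5 s of the clip
(minimum sliding energy at 10 ms steps) serves as the reference.

The raw binary mask is smoothed by convolution with an equal-weight
2 (frequency) × 4 (time) kernel and kept *soft* (values in [0, 1]) rather
than re-binarized; the graded attenuation suppresses isolated one-cell
openings that would otherwise ring as musical noise. Consequences worth
knowing:

- A narrow-band component loses part of its spectral skirt (the kernel
  halves the gate at the band edge), which caps the reconstruction SNR of
  a *continuous* pure tone near 25 dB. Realistic calls, which occupy many
  cells, are essentially unaffected.
- With `n_std → −∞` the pipeline is the identity on interior samples up to
  border-row smoothing; with `n_std → +∞` it returns silence.
- Self-referenced pure noise is attenuated to roughly 14 % of its input
  RMS, not to zero: by construction the loudest ~7 % of noise cells lie
  above a mean + 1.5 σ gate.

Inverse transform: weighted overlap-add with window-squared normalization.
Samples whose accumulated window coverage is below half the interior level
(the first and last partial-overlap ramps, ~0.1 s at the defaults) are set
to zero instead of being divided by their tiny weights — for an untouched
spectrum that division is exact, but after masking it amplifies edge
leakage without bound. Interior samples round-trip to machine precision.

## MFCC features

The Mel mapping is `m = 2595 · log10(1 + f/700)`. The filter bank places
M + 2 boundary points equally spaced in Mel between 0 and Nyquist; filter m
rises linearly from boundary m to an apex of 1 at boundary m + 1 and falls
to zero at boundary m + 2 (the piecewise-triangle definition; adjacent
triangles sum to 1 between apexes). Energies are pooled per frame, floored
at 1e−10 before the log to guard silent frames, and cosine-transformed with
the unnormalized kernel `cos(n (m − ½) π / M)` for n = 1..M — a DCT-II
family without the DC row, so a uniform gain shift of the waveform leaves
every retained coefficient unchanged. All M coefficients are kept, since
the classifier input is the full M × T matrix; a `logmel` switch skips the
DCT for experiments on the ambiguity between cepstral and log-Mel inputs.

The time axis is right-padded with zeros (or right-truncated) to a fixed
frame target (default 2000), making every clip the same tensor shape.

## Classifiers and Adadelta

Both models are plain sequential CNNs over the single-channel feature
matrix: 3 × 3 convolutions ('same', stride 1), ReLU, non-overlapping max
pooling, a dense ReLU head, and a Softmax output; categorical
cross-entropy loss. The binary gate uses three blocks (16/32/64 filters,
pool 2 × 4) and a 64-unit head; the behavioral model four blocks
(16/32/64/128, pool 2 × 2) and a 128-unit head, so it is strictly deeper
and larger at any input size. Exact depths and pool shapes are
configuration, not contract; the only fixed constraints are the activation
pair (ReLU/Softmax) and the behavior model's larger parameter count.

Adadelta is implemented from its recursions with decay γ = 0.95 and
smoothing ε = 1e−7 applied inside both square roots; the squared-gradient
average uses the standard `(1 − γ)` innovation weight. The first step from
zero accumulators is `−√ε/√((1−γ)g² + ε)·g`, so updates start small and
self-scale — no learning rate exists. The same update routine drives both
the functional single-state API and the per-tensor training optimizer.

Training uses a deterministic stratified 80/20 holdout, per-epoch shuffling
from one seeded generator (bit-reproducible for a fixed seed), batch size
32, 60 epochs by default (accuracy typically converges well before 40),
final-epoch model selection, and optional class weights (off by default,
preserving natural class imbalance). Inputs are standardized per
coefficient row with statistics fitted on the training split and stored in
the checkpoint; raw log-energy cepstra have magnitudes of order 10²,
which would otherwise make the scale-free optimizer's early progress
needlessly slow. Checkpoints are .npz weight archives with a JSON sidecar
describing the architecture.

## Synthetic data

The generator emulates the *structure* the pipeline assumes, not bovine
physiology: harmonic stacks with class-distinct signatures — long rising
fundamental sweep (estrus-like), trains of short pulses
(food-anticipating-like), short broadband noisy bursts (cough-like), and
flat-fundamental calls (normal) — embedded 2–3 s into 5 s clips, with
fundamentals of 80–300 Hz and up to 12 harmonics at 1/h rolloff. These
values are plausibility conventions, documented as such. Noise kinds:
broadband white noise, low-frequency hum low-passed below ~400 Hz (≥ 90 %
of its power under the band limit), transient inharmonic metal clangs, and
speech-like chirp sequences. Noise is mixed at an exact whole-clip RMS SNR.
An `imbalance` mode reproduces a 207/178/56/456 four-class corpus
(total 897); a `hard` mode narrows the inter-class contrasts.

Because the class signatures are deliberately separable, high accuracy on
this corpus demonstrates that the pipeline is wired correctly end to end
and that the features/optimizer can express and learn the distinctions —
it says nothing about accuracy on real barn recordings, where class
overlap, reverberation, and labeling noise dominate.

## Desk-scale benchmark

The acceptance benchmark (tests and `scripts/acceptance.py`) uses 100
clips per call class plus 100 non-vocal clips at 16 kHz, the full spectral
gate (2048/2048/256), features at 32 Mel bands × 64 frames (hop 1280, so a
whole 5 s clip fits the frame target), and 40 training epochs at batch 32.
These sizes keep a full two-model training run in the tens of seconds on
one CPU while leaving both tasks comfortably learnable; the feature
resolution and epoch count are the package's desk-scale configuration, not
tuned quantities. A permuted-label control at the same scale verifies the
training loop cannot manufacture accuracy: validation accuracy stays
inside the binomial 95 % band around chance.

## Numerical details and edge cases

- dB magnitudes use a 1e−12 floor inside the log; exact zeros map to
  −240 dB rather than −inf.
- Noise-profile standard deviations are population (ddof 0) statistics; a
  single-column reference is rejected as degenerate.
- Reported percentages are truncated, not rounded, to two decimals
  (91.388… prints as 91.38); full precision is kept internally.
- Max-pool gradients split ties equally so gradient mass is conserved;
  pooling drops trailing rows/columns that do not fill a window.
- All-zero clips are representable (peak level −inf) but cannot be level-
  measured or SNR-targeted; both raise a silent-segment error.
- PCM-16 WAV round trips are exact to one quantization step (scale 32768,
  symmetric clip); float WAVs round-trip losslessly. Multichannel input is
  downmixed by channel averaging.

## Known limitations

- The gate models stationary noise only; nonstationary interference
  (moving machinery, overlapping animal calls) is outside its assumptions.
- The monitoring flow treats each WAV file as one captured event; live
  capture and transport are out of scope.
- The mel-filter contract rejects configurations where a filter has no
  supporting FFT bin (e.g. 128 bands on a 64-point FFT) instead of
  silently producing empty filters.
- Continuous-tone reconstruction is SNR-limited by mask smoothing, as
  noted above.
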