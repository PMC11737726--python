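# Methods

This note documents the models, defaults and design decisions behind
`coopvox`, and what its synthetic benchmark does and does not show.

## Synthetic vocalization model

Real barn recordings of the six call classes are not redistributable, so
the package generates its own. Each class is realized as a `CallSpec`:
syllables repeat at `repetition_rate` (Hz), each lasting
`syllable_duration` (s) under a Hann gate; the carrier is a
phase-continuous stack of `n_harmonics` partials (amplitudes 1/h) on a
fundamental drawn uniformly from `f0_range` once per syllable period and
swept linearly at `fm_sweep` (Hz/s) within the syllable (held constant
after the syllable ends); `am_depth` ∈ [0, 1] interpolates between a
continuous tone (0) and a fully gated syllable train (1); the clip is
peak-normalized to `amplitude_db` (dBFS). `n_harmonics = 0` selects
band-limited noise bursts (4th-order Butterworth bandpass over
`f0_range`) — calls with no fundamental.

Only the qualitative characters of the six call types are normative;
the numeric table is this package's parameterization:

| class | f0 band (Hz) | syllable (s) | rate (Hz) | harmonics | level (dBFS) | sweep (Hz/s) |
|---|---|---|---|---|---|---|
| C1 contentment cluck | 300–600 | 0.12 | 4 | 5 | −6 | 0 |
| C2 hunger piping | 2500–3500 | 0.06 | 8 | 2 | −6 | 0 |
| C3 exploratory peeping | 1550–1950 | 0.08 | 3 | 2 | −18 | 600 |
| C4 prelaying crackle | 500–4000 (noise) | 0.03 | 10 | 0 | −8 | 0 |
| C5 rooster crow | 550–700 | 1.2 | 0.5 | 4 | −3 | 900 |
| C6 alarm/distress | 1050–1350 | 0.10 | 6 | 5 | −3 | 0 |

Rationale: low steady clucks vs high short peeps gives tonal classes
pairwise class-mean fundamentals ≥ 150 Hz apart (C4 is broadband, C5 is
identified by its long loud upward sweep, so both are exempt); C3 is
quiet (−18 dBFS) with a small rising inflection; harmonic counts are
capped so no partial crosses the 8 kHz Nyquist at 16 kHz. Partials that
would cross Nyquist (possible with user-supplied specs) are muted with a
warning rather than aliased.

Clips are 2.0 s of 16 kHz mono audio. The source study fixes the
2-second segmentation; it does not state a sample rate or bit depth, so
the package defaults to 16 kHz / 16-bit PCM WAV, the standard capture
format for embedded audio front ends. The full composition is
C1:1200, C2:480, C3:360, C4:720, C5:600, C6:240 (3600 clips); the `mini`
preset divides every count by 12 (300 clips) so the complete pipeline
runs in seconds. Splits are per-class: indices are shuffled with the
dataset seed and floor(n/5) go to validation (train:val = 4:1).

**Barn noise.** Continuous ventilation gives barns a characteristic
noise floor. The model is a fan hum (fundamental 120 Hz with 5 harmonics
at 1/k amplitude, random phases) plus pink broadband noise (1/√f
spectral shaping), power-balanced 50/50 and scaled so the realized
10·log₁₀(P_signal/P_noise) equals the requested SNR exactly; if the
mixture exceeds full scale the whole clip is renormalized, which
preserves the ratio. A zero-power clip is rejected (SNR undefined).

**Determinism.** Every sample value is a function of (composition,
seed): per-clip seeds are drawn from one seeded generator in fixed class
order, so a manifest plus its seed reproduces the dataset bit-exactly.

**What the generator does not emulate:** real hen acoustics (formant
structure, individual variation, overlapping calls, reverberation,
non-stationary barn events). Passing tests show the pipeline is correct
and that the synthetic task is learnable — not that the trained network
would transfer to real recordings.

## Wavelet denoising

The DWT is implemented directly from the two analysis summations with
the db1/Haar filter pair and **periodic boundary extension**, which
keeps the filter bank exactly orthonormal: coefficient counts halve per
level, energy is conserved to machine precision, and synthesis (the
adjoint) is an exact inverse. Odd-length inputs are zero-padded by one
sample per level and trimmed on reconstruction. Defaults: J = 4 levels
(or the maximum the length permits), soft thresholding with the
universal threshold T = σ√(2 ln N), σ = MAD/0.6745 of the finest detail
band — standard, fully reproducible wavelet shrinkage; hard
thresholding, fixed thresholds and per-level σ are selectable. The
approximation band is never thresholded. Because shrinkage only reduces
coefficient magnitudes of an orthonormal transform, denoising is
non-expansive in energy.

With J = 4 at 16 kHz the protected approximation band covers roughly
0–500 Hz; Haar's soft frequency selectivity means tones near the band
edge are partially shrunk. The denoising unit tests therefore probe with
tones well inside the band (e.g. 250 Hz at 0 dB white noise: > 3 dB SNR
gain; a clean 100 Hz tone: < 10% distortion). PyWavelets
(`mode="periodization"`) serves as an independent oracle in the tests;
the implementation itself stays self-contained.

## MFE features

Frames of 25 ms with 10 ms hop (Hamming window), FFT size the next power
of two (512 at 16 kHz), 40 triangular filters from 0 Hz to Nyquist with
centers equispaced on m = 2595·log₁₀(1 + f/`mel_break`). The canonical
pairing of the 2595 coefficient uses `mel_break` = 700 Hz, the default;
a 100 Hz knee is selectable for compatibility with nonstandard printed
variants of the formula. Frame count is floor((n − frame)/hop) + 1 with
no tail padding — a 2 s clip at 16 kHz yields exactly 198 frames. Band
energies are the matrix product of frame power spectra with the filter
weights; log compression adds a floor of 1e−10 to bound dynamic range
without affecting voiced frames.

## Classifier

Input (198 frames × 40 bands), convolution along time with bands as
channels. Blocks: Conv1D(k=3) → ReLU → MaxPool(2) → Dropout with
32/64/128 filters and dropout 0.25/0.25/0.5; then Flatten →
Dense(64, ReLU) → Dense(6, softmax) trained with categorical
cross-entropy. The six-class task requires a softmax output; a sigmoid
head would only suit a one-vs-rest binary reading. Unstated
hyperparameters follow small-audio-CNN convention: Adam at 1e−3, batch
32, early stopping on validation loss with patience 5 and
best-weight restore. Features are z-scored per band with training-split
statistics persisted on the model. He-initialized weights, shuffling and
dropout all draw from one seeded generator, so a (config, seed) pair
reproduces the training history exactly on one thread. The default
network has ~224k parameters — under 1 MB at int8, the ROM class of
milliwatt audio NPUs.

## Quantization and pruning

Quantization is simulated: weights stored as symmetric per-tensor int8
(scale = max|w|/127, guard scale 1 for all-zero tensors) and dequantized
for inference; every layer activation is fake-quantized through an
affine per-tensor int8 grid whose range is calibrated from min/max over
a calibration set (first 100 training clips). The contract under test is
accuracy after quantization; integer kernels and device deployment are
out of scope, as is quantization-aware training. Pruning zeroes the
smallest-magnitude fraction of each weight tensor (unstructured,
biases untouched), with cutoff ties resolved so the realized sparsity is
within 1/|tensor| of requested.

## Evaluation

Confusion matrices use rows = actual, columns = predicted, class order
C1..C6. Per-class metrics are one-vs-rest; zero denominators yield 0
with a flag rather than an exception, so degenerate splits report
cleanly. Micro accuracy equals trace/total and, identically,
support-weighted recall. Comparison against printed reference tables
rounds computed values half-away-from-zero to 3 decimals (the tables'
apparent convention) and checks |diff| ≤ 5e−4.

Both published reference tables ship as count-matrix fixtures with their
printed metric rows. The MFE table reproduces 23/24 cells; its C6 FPR is
inconsistent with its own matrix (derived ≈ 0.005, printed 0.05). The
MFE+DWT table's C2 row sums to 481 (stated class size: 480) and only C2
recall, C4 F1 and C5 recall reproduce; all other cells are encoded as a
known-exception list. `fixtures verify` requires the observed mismatch
set to equal the documented set exactly — a drift in either direction
fails.

## Experiments and controls

`run_experiment` executes raw and denoised arms on the identical
dataset, split and training seed, and reports validation metrics and
deltas. The desk-scale problem sizes are: mini composition (300 clips,
240/60 split), 10 training epochs, three dataset seeds for the 0 dB
comparison. At these settings the synthetic classes are separable enough
that both arms reach ceiling even at 0 dB SNR — the two-arm comparison
therefore verifies the directional claim (denoising does not hurt), while
the denoising stage's signal-level benefit is established directly by
the SNR-gain tests. A trivial nearest-class-mean classifier on
time-averaged mel spectra already exceeds 80% on clean clips, which is
by design: it certifies learnability independently of the CNN.

The null control trains on randomly permuted labels and must land within
0.1 of the 1/6 chance level. It uses a class-balanced desk-scale
composition (50 clips per class): with the study's imbalanced mix a
label-shuffled learner can still reach ~1/3 accuracy by predicting the
majority class, so class balance is a precondition for the 1/6 reference
point.

## Known limitations

- Synthetic calls are far cleaner and more stereotyped than real barn
  audio; absolute accuracies here do not predict field performance, and
  the published accuracy gap between the raw and denoised pipelines is
  not numerically reproducible without the original recordings.
- Only the db1 wavelet is built in; the periodized transform structure
  would accept other orthonormal filter pairs but none are shipped.
- The CNN runs in float; int8 behavior is simulated, not bit-exact
  against any particular integer runtime.
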