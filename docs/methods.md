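# Methods

## Overview

`pcgscreen` implements a three-class heart-failure screening pipeline for
phonocardiogram (PCG) signals: recordings are down-sampled to a 600 Hz
working rate, S1 onsets are localized with a duration-dependent hidden
semi-Markov model (HSMM), fixed-length frames anchored at successive S1
onsets are min-max normalized, and a gated recurrent unit (GRU) network —
compared against LSTM, FCN and feature+SVM baselines — assigns each frame
to one of {normal, HFpEF, HFrEF} under tenfold cross-validation.  Because
no public dataset pairs heart-failure labels with PCG audio, the package
includes a first-class synthetic generator so the complete chain is
trainable and testable from a single seed.

## Synthetic phonocardiograms (`pcgscreen.synth`)

Each cardiac cycle is the sum of two Gaussian-amplitude-windowed sinusoid
chirps: S1 at the cycle start (band 10–200 Hz, default duration 0.12 s) and
S2 at `systole_fraction × cycle` (band 20–250 Hz, 0.10 s).  Cycle durations
are drawn independently and uniformly from [0.6, 0.8] s; the default
systole fraction is 0.42.  These values are physiologically plausible
round numbers for adult heart sounds.  White Gaussian noise is added at a
configurable SNR (default 25 dB, a clean-stethoscope regime).  The chirp
sweeps downward inside the inner portion of its band so that component
energy stays well within the nominal band (tested: ≥ 80% of S1 energy in
10–200 Hz).

The three screening classes are *acoustic surrogates*, not clinical
models:

| class  | S1 amp | S2 amp | band scale (S1/S2) | low-freq | murmur |
|--------|--------|--------|--------------------|----------|--------|
| normal | 1.0    | 0.8    | 1.00 / 1.00        | 0        | 0      |
| HFpEF  | 0.9    | 1.15   | 0.75 / 0.85        | 0.25     | 0.12   |
| HFrEF  | 0.5    | 1.0    | 0.90 / 1.00        | 0.40     | 0.25   |

The choices encode a weakened first sound for reduced ejection fraction
and a shifted spectral balance plus soft systolic murmur for preserved
ejection fraction.  Because frames are min-max normalized, absolute
amplitude is not informative; the learnable signal is the S1:S2 ratio,
spectral content and murmur floor.  What passing tests show is that the
*pipeline* can learn class-conditional acoustic structure at realistic
SNR — not that these surrogates match real HF acoustics, whose effect
sizes are unknown.

Features of real data deliberately not emulated: S3/S4 sounds, murmur
taxonomies, respiration and sensor artifacts, inter-subject variability
beyond the per-cycle jitter, and rate variability beyond uniform jitter.

All randomness flows through `numpy` generators seeded from the config;
a dataset is reproducible from its base seed (per-recording seeds are
spawned from a `SeedSequence`).

## Segmentation (`pcgscreen.segmentation`)

The segmenter follows the logistic-regression HSMM recipe that is standard
for heart-sound segmentation:

- **Features** (50 Hz feature rate): homomorphic envelope (low-passed log
  magnitude of the analytic signal, 8 Hz second-order Butterworth,
  zero-phase), Hilbert envelope, and a coarse 25–140 Hz band-power
  envelope; each channel min-max scaled to [0, 1].  Near-constant channels
  map to zeros to avoid amplifying float noise on silent input.
- **Emissions**: one-vs-rest logistic regressions per state
  (S1, systole, S2, diastole), posteriors renormalized per tick.  Trained
  on synthetic recordings with known state paths — no hand-labeled corpus
  exists for this setup.  Note the two silent states are not separable
  from instantaneous envelopes; the duration model disambiguates them.
- **Heart rate**: cycle length from the autocorrelation peak of the
  homomorphic envelope in a 0.5–1.0 s lag window.  The systole fraction is
  returned as a fixed prior (0.42); it is not reliably estimable from the
  envelope alone.
- **Durations**: truncated Gaussians in feature ticks.  Means are tied to
  the estimated cycle via fixed fractions (S1 = 0.12 s,
  systole = 0.42·cycle − 0.12 s, S2 = 0.10 s, diastole = remainder);
  sd = max(0.7 ticks, 18% of mean); support clipped to
  [max(1, mean − 3 sd), mean + 3 sd].
- **Decoding**: duration-dependent Viterbi over the deterministic cycle
  S1 → systole → S2 → diastole.  The first and last runs may be truncated
  by the recording edges and are scored with the duration survival
  probability P(D ≥ d); interior runs use the exact duration probability;
  the initial state is uniform.  Ties break toward the shorter duration,
  then the earlier state in cyclic order, so decoding is deterministic.
  The implementation is validated against exhaustive path enumeration on
  tiny instances (score equality to 1e-9, path equality up to ties).

S1 onsets are the starts of decoded S1 runs, in seconds.  On clean
synthetic recordings (SNR 30 dB, 20 cycles) onset sensitivity and positive
predictive value are ≥ 95% at a ±60 ms tolerance — the tolerance is half
the S1 duration, i.e. a detection must land inside the correct sound.

## Preprocessing and framing

Resampling uses polyphase rational-ratio filtering with a Kaiser-windowed
low-pass (β = 5), the standard anti-aliased choice; the 600 Hz working
rate satisfies Nyquist for the S2 band.  No denoising stage is applied, by
design.  Frames start at the S1-onset sample (`floor(onset × rate)`,
half-open `[start, start+L)`), span exactly `round(frame_length × rate)`
samples (960 at 1.6 s × 600 Hz; 480 at 0.8 s) and are dropped, not padded,
when they would run past the end of the recording — padding would distort
the min-max normalization.  Each frame is normalized per-frame to

    X = (x − x_min) / (x_max − x_min),

which is idempotent, invariant under positive affine rescaling, and maps
constant frames to zeros (logged as degenerate).  Frame-local rather than
recording-global extrema are used; the alternative would reintroduce the
inter-recording amplitude differences normalization is meant to remove.

## Classifiers (`pcgscreen.models`)

The recurrent cells implement the screening recipe's printed equations
verbatim, including two deliberately non-standard conventions:

- GRU: `h = z ⊙ h_prev + (1 − z) ⊙ h̃` — the update gate multiplies the
  *previous* state (many libraries use the complement), with
  `h̃ = tanh(b + U x + W (r ⊙ h_prev))`.
- LSTM: the cell candidate passes through a **sigmoid**, not tanh
  (`candidate="tanh"` is available as a variant flag).

The reference architecture is 2 recurrent layers × 64 units feeding a
3-unit softmax head.  Training minimizes softmax cross-entropy (log-sum-exp
form) plus an L2 penalty on weight matrices only (λ = 1e-4), with Adam at
learning rate 0.001, batch size 64, 50 epochs, no early stopping.  Weights
initialize uniform ± 1/√fan_in from a fixed seed; hidden states start at
zero.  The FCN baseline uses three conv blocks (128/256/128 filters,
kernels 8/5/3, "same" padding, stride 1) each followed by batch
normalization (ε = 1e-5, running-stat momentum 0.9) and ReLU, then global
average pooling into the softmax head.

Everything trains on an in-package reverse-mode autograd over numpy
arrays (float32 computation; the equation-level `gru_step`/`lstm_step`
reference functions are float64 and are cross-checked against independent
element-wise evaluators to 1e-12, and the autograd forward pass against
the step functions).  Gradients are additionally verified against central
finite differences.

Frames are consumed one scalar sample per timestep by default, exactly
matching "normalized frames as input".  A chunked-input option reshapes a
960-sample frame into 96 steps × 10 samples; it is mathematically a
different input embedding, converges to the same accuracy on the synthetic
task, and is roughly 10× faster, so the bundled evaluation scripts use
chunk 10.

## Feature bank and SVM baseline (`pcgscreen.features_svm`)

The hand-crafted bank (16 features) is a documented generic substitute for
an unavailable reference set: frame energy, low/high (10–90 / 90–250 Hz)
band-energy ratio, zero-crossing rate, spectral centroid and bandwidth,
sample entropy (m = 2, r = 0.2 sd, input decimated to ≤ 240 samples since
SampEn is O(n²); constant input → 0 by convention), five relative
wavelet-band energies (db4, level 4) and five Mel-cepstral means (16-filter
mel bank to 300 Hz, DCT-II).  Feature screening uses Tamhane's T2: all
pairwise Welch t statistics with Welch–Satterthwaite degrees of freedom and
a Sidák adjustment over the k = 3 pairs (p_adj = 1 − (1 − p)³); a feature
is selected when its smallest adjusted P < 0.001, keeping at most the best
three.  The SVM is one-vs-one RBF with features standardized on the
training fold and (C, γ) grid-searched over powers of four
(C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³) by internal 3-fold cross-validation on the
training fold only; ties go to the first grid point.

## Evaluation (`pcgscreen.evaluation`)

Tenfold cross-validation: frames are split 90/10 per fold, stratified by
class at the frame level (this mirrors a frame-level split; because
consecutive frames of one recording overlap, frame-level splitting can
leak recording identity — a `grouping="recording"` mode using grouped
folds is provided for leakage-free estimates).  Within each fold a
stratified 20% of the training frames is held out for validation
monitoring.  Train/validation/test disjointness is asserted on every run.
The pooled confusion matrix uses rows = true, columns = predicted;
precision is the column-wise and recall the row-wise diagonal fraction;
fold-accuracy spread is mean ± sd with the n − 1 denominator.
`sweep` covers the layers × units grid ({1,2,3} × {8,16,32,64,128}) and
`compare_frame_lengths` runs paired CV at 0.8 s vs 1.6 s with aligned fold
seeds.

## Problem sizes in the bundled runs

The acceptance script and the end-to-end tests synthesize 11 recordings
per class × 20 cycles (≈ 600 frames at 1.6 s), train the 2 × 64 GRU with
the full 50-epoch recipe at chunk size 10, and fit emissions on a separate
6-recording synthetic set.  These sizes were chosen as the smallest at
which the tenfold estimate is stable; the generator scales to larger
corpora by changing two config fields.

## Known limitations

- Class surrogates are free parameters, not estimates of real HF
  acoustics; reported accuracies characterize the pipeline, not clinical
  performance.
- The segmenter assumes a quasi-stationary rhythm (single dominant
  autocorrelation peak); with two interleaved tempos it locks to the
  dominant one.
- Default frame-level CV shares recordings between train and test folds
  (see above); grouped mode is stricter and typically scores lower.
- Emission training requires ground-truth state paths, which only the
  synthetic generator provides.
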