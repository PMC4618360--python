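# Methods

## Problem and model

Given epoched multichannel EEG `(n_trials × n_channels × n_samples)` with
class labels (imagined movements), the package selects the smallest channel
subset whose band-power features achieve the maximal cross-validated
classification accuracy. The underlying physiological model is event-related
desynchronization/synchronization (ERD/ERS): imagining a movement attenuates
the power of ongoing mu (~8–12 Hz) and beta (~18–26 Hz) rhythms over
contralateral sensorimotor cortex. Discriminative information is therefore
sparse in both space (few electrodes) and frequency (narrow, subject-specific
bands), which motivates a per-(channel, band) feature representation and a
feature-level selection algorithm that is afterwards aggregated to channels.

## Pipeline stages and parameters

**Surface Laplacian** (`preprocess.laplacian_filter`). Output channel
`j` is `V_j − (1/n) Σ_{k∈S_j} V_k` with `S_j` the montage neighbor set. All
channels are transformed simultaneously from the raw input — never
sequentially in place — so the operator is a fixed linear map: it is linear,
annihilates spatially constant signals, and each output depends only on the
channel and its neighbors. The bundled 61-channel 10–20-style montage is a
schematic grid stand-in (4 neighbors interior, 2–3 at the periphery), not a
measured head model; any subset of it, or any user YAML montage, can be
loaded.

**Resampling** (`preprocess.downsample`). Integer-factor decimation only,
preceded by a zero-phase order-8 Butterworth low-pass at 0.4 × target rate
(> 40 dB at the new Nyquist). Correct anti-aliasing is a hard requirement for
band-power features, so non-integer factors are rejected rather than
approximated.

**Execution-window cropping** (`preprocess.crop_execution`). Half-open
window `[start, end)` with floor-based sample indexing. Which part of a trial
is "execution" is paradigm-specific, so the window is always explicit.

**Constant-Q filter bank** (`feature_bank.design_constant_q_bank`).
Defaults: start center 6.0 Hz, ratio 8/7, fractional bandwidth 0.25,
13 bands. These three numbers jointly reproduce the conventional 13-band
table (5.25–6.75 … 26.07–33.51 Hz) at two-decimal rounding, and give the
bank its two structural properties: constant fractional bandwidth, and each
band's lower edge coinciding with the previous band's center (guaranteed
overlap). All parameters are exposed for non-default banks.

**Band-pass realization.** 4th-order zero-phase Butterworth (applied
forward–backward). The contract is a magnitude-response one — no passband
ripple, ≥ 20 dB one octave outside the edges — not bit-exactness of any
particular filter; tests assert the response, not coefficients.

**Envelope features** (`feature_bank.extract_features`). Feature
`(trial, channel, band)` = mean over the trial of the magnitude of the
analytic signal of the band-passed channel. Filtering is trial-wise; the
average runs over the full trial with no edge trimming (edge transients are
part of the feature definition; closed-form comparisons in tests use
interior samples only). Trials must hold at least ~3 cycles of the lowest
band. Features concatenate channel-major, band-minor: feature `i` ↔ channel
`i // n_bands`, band `i % n_bands`.

**Normalization** (`feature_bank.minmax_normalize`). Per-feature min–max
to (−1, 1). Parameters are fit on training folds only and applied to test
folds, where values may legitimately leave the target range and are left
unclipped; clipping would leak no information but would distort test-set
geometry. Constant features map to the range midpoint with a warning.

## Relieff and IterRelCen

Weights follow the k-nearest hits/misses update with empirical class priors;
on two classes it reduces to classic Relief. The per-feature difference is
normalized by the feature's training range, which makes both the weights and
all distance computations invariant under per-feature positive affine
transforms. Key numerical choices:

- **Aggregate distance** for neighbor search and center ordering is the sum
  of per-feature range-normalized absolute differences (Manhattan on
  range-scaled values) — the same quantity the weight update accumulates, so
  one metric governs the whole algorithm. The center-distance rule
  `min |S_i − Ct|` does not itself pin down a norm; Manhattan is the
  package's choice and is applied uniformly.
- **Ties** (equal distances, equal weights) always break by ascending index.
  Reproducibility over elegance.
- **Targets.** Plain Relieff draws `m` targets uniformly without replacement
  (seeded). IterRelCen is fully deterministic: each class contributes
  `round(m × class share)` targets in order of distance to the class center,
  recomputed on the surviving features each iteration.
- **Iteration.** Each pass recomputes weights from scratch on the surviving
  features (ranges and class centers included), removes the `N` smallest,
  and evaluates the survivors; the initial full set is also evaluated once,
  so either convention ("evaluate before" vs "only after removal") can be
  read off the trace. With `N = n_features` and a fixed target list the loop
  degenerates to a single Relieff pass, which tests verify bit-for-bit.
- **Defaults:** `k = 10`, `m` = all training samples, `N = 10`.
- **Validity bounds.** Every class must have ≥ k+1 members; weights on
  normalized input lie in [−1, 1] because each update term averages
  quantities in [0, 1].

## Evaluation protocol

Stratified tenfold outer CV (deterministic given a seed; per-fold class
counts within 1 of proportional). Within each outer fold: normalization fit
on the training fold; IterRelCen run on the training fold with an inner
stratified 5-fold CV SVM accuracy as its evaluator (using the outer test
fold there would leak); outer test accuracy recorded at every step of the
elimination schedule, which is identical across folds. Reported accuracy per
step is the exact arithmetic mean of fold accuracies.

The SVM is an RBF-kernel soft-margin machine, `C = 1`,
`gamma = 1/n_features` by default (the multiclass case uses one-against-one
pairwise classifiers, `K(K−1)/2` of them). These hyperparameters are
deliberately plain; a grid search inside the training fold can be layered on
by the caller without touching the protocol.

**Optimal channels.** Among steps of maximal mean accuracy (ties within
1e−12) the one mapping to the fewest channels wins (then fewest features).
Because outer folds disagree on feature identities, the *reported channel
set* is a point estimate from one final IterRelCen pass over the full data
at the chosen step size, while the accuracy attached to it remains the
cross-validated one; both are returned.

**Reporting arithmetic.** A channel's weight is the sum of its surviving
features' weights (discarded channels get 0); the accuracy-vs-channels curve
adds channels one by one in descending weight order, using all bands of each
added channel, the weights coming from the first (full-set) weight pass —
the only pass in which every channel still has a weight. Band-usage counts
report, per band, how many distinct channels kept that band.

## Synthetic data

The generator emulates what the selection method needs to be tested against,
not cortical physiology: each channel is pink noise (1/f, spectral shaping,
exponent 1, unit amplitude) plus white sensor noise (sd 0.5) plus ongoing
band-limited oscillations (band-passed white noise, unit RMS, amplitude 1.0);
at the informative channels of a class the oscillation amplitude is
multiplied by the attenuation factor (< 1) during that class's trials —
amplitude attenuation of ongoing activity being the simplest mechanism with
the ERD signature. The default benchmark: 20 channels on a 4 × 5 grid,
2 classes × 100 trials, 200 Hz, 3 s trials, mu-band (8–12 Hz) attenuation
0.5 (power × 0.25) on channels {6, 8} for class 0 and {16, 18} for class 1 —
a contralateral pair per hemisphere analog, none mutually adjacent so the
Laplacian does not mix planted signals. One master seed drives all
sub-streams.

What it does *not* model — volume conduction beyond the Laplacian's reach,
ocular/muscular artifacts, non-stationarity across a session, subject
variability in band location — bounds what passing tests show: recovery
results demonstrate correctness of the selection machinery under the stated
signal model, not expected accuracy on recorded EEG.

## Problem sizes used in the test and acceptance runs

Recovery experiments run the full 200-trial, 20-channel benchmark over 20
generator seeds for the channel-weight check, 3 seeds for the
accuracy-vs-channels curve, and 1 permuted-label control; the nested
selection CV is exercised on smaller planted feature matrices (tens of
features) where its behavior is checked step by step. These sizes were
chosen so the statistical claims (≥ 90 % recovery over seeds, binomial
chance bounds) remain meaningful.

## Known limitations

- The elimination loop calls the evaluator once per iteration and fold;
  with 767 features and `N = 10` that is ~77 SVM CV evaluations per fold —
  minutes, not seconds, on a full cap. `inner_folds=0` runs the selection
  trace without inner evaluation when only the weights are needed.
- EDF support targets uniform-rate EDF/EDF+ recordings; mixed-rate files are
  rejected. The EDF writer is a minimal 16-bit implementation intended for
  fixtures and export, not annotation-rich EDF+.
- The selection operates offline on complete epochs; streaming/online use is
  out of scope.
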