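# Methods

This note documents the models, numerical choices and open design
decisions behind `tremorsep`, and what the synthetic-data generator does
and does not establish.

## Signal model and simulator

A recorded channel is modeled as

```
mixed(t) = voluntary(t) + tremor(t) + noise(t) + drift·t,   fs = 100 Hz
```

with a fraction of interior samples subsequently replaced by NaN
(missing-data markers). Ground-truth components are kept uncorrupted so
decomposition quality is measurable against them.

**Voluntary component** — a random superposition of 3–6 sinusoids with
frequencies uniform in [0.2, 2.5] Hz and random phases, peak-scaled to the
profile amplitude; this keeps ≥ 95% of periodogram power below 3 Hz. The
"drinking" activity adds a slow raised-cosine reach-and-return trajectory
(four cycles per recording, the dominant term), because that action is
dynamic and multi-phase where the three postural actions are static.

**Tremor component** — an amplitude- and frequency-modulated tone. The
carrier is drawn once per subject, uniform in [3.5, 9] Hz; a slow
(0.1–0.3 Hz) sinusoidal wobble of ±0.3 Hz modulates the instantaneous
frequency, and a 10–50% depth amplitude modulation emulates the waxing and
waning of pathological tremor. ≥ 95% of power stays inside 3–10 Hz.

**Defaults and units.** Amplitudes are in degrees: voluntary 1–2° for the
postural actions and 15° for drinking; tremor 1.2–2° with a ±40%
per-subject factor; white Gaussian sensor noise with std 0.05°; linear
drift 0.1°/s; 1% missing samples (never at the endpoints, so
interpolation stays bounded). No amplitude statistics exist for the
clinical recordings this emulates, so these are realistic free choices for
AHRS orientation data, not calibrated values.

**What a green test does not establish.** The simulator produces
stationary, single-carrier tremor with Gaussian noise. Real tremor is
non-sinusoidal (harmonics), non-stationary across a recording, correlated
across axes and body parts, and sensor noise need not be white. Results on
the simulator demonstrate that the pipeline's machinery works and recovers
known structure; they do not predict clinical performance numbers.

## Preprocessing

Missing samples are filled with a shape-preserving piecewise cubic Hermite
interpolant (PCHIP) through the present samples; endpoints must be present
(interpolation, never extrapolation). The least-squares straight line is
then removed. Order is fixed as interpolate → detrend because detrending
needs complete data. Note that detrending a finite record absorbs a small
part of any low-frequency oscillation into the fitted line (order 1e-2 of
the component amplitude for a 10 s record); this is inherent to
least-squares detrending, not an artifact.

## EMD and EEMD

One IMF is extracted by sifting: subtract the mean of the natural-cubic-
spline envelopes through local maxima and minima, repeating until the
relative squared change between consecutive candidates,
`D = Σ|h_prev − h_curr|² / Σ|h_prev|²`, falls below 0.2 **and** the
candidate satisfies the IMF counting criterion (zero crossings and extrema
differ by ≤ 1), capped at 50 sifts. The threshold 0.2 is the standard
Cauchy-type choice; the counting requirement is enforced because an IMF is
defined by it, and the Cauchy criterion alone leaves noisy first IMFs with
count gaps of ~8.

Numerical details:

- **Extrema**: strict three-point comparison; a flat plateau that is a
  local extremum contributes its midpoint once; endpoints are never
  extrema.
- **Envelope boundaries**: the two extrema nearest each end are mirrored
  about the endpoint before spline fitting — the common guard against
  edge swing. With fewer than four knots the envelope falls back to
  quadratic/linear interpolation.
- **Termination**: decomposition stops when the residual has fewer than
  two maxima or two minima (monotone in the practical sense) or at 12
  IMFs. Completeness is exact by telescoping construction.

EEMD decomposes N = 100 copies of the signal, each perturbed by white
Gaussian noise with std 0.2 × std(x) (the Wu–Huang convention; both
configurable), member n drawing its noise from seed + n. IMFs are aligned
by index and zero-padded to the ensemble-wide maximum count before
averaging; residuals are averaged likewise. The reconstruction error of
the ensemble mean is exactly the mean of the injected noise: RMS
0.2·std(x)/√N, with the pointwise maximum over a 1000-sample record near
3.5× that value (extreme-value statistics). With zero noise and one member
EEMD reduces bitwise to EMD. Ensemble-mean IMFs are *not* required to pass
the counting criterion — averaging breaks it, a known property of EEMD.

## Benchmarks and combination selection

Reference tremulous/voluntary signals come from a 4th-order Butterworth
band-pass (3–10 Hz) and low-pass (3 Hz), applied forward–backward
(zero phase, effectively 8th-order magnitude) so the benchmark has no
phase shift; a causal single-pass option exists behind a flag. Sums of
IMFs are scored with log10(RMSE) against the benchmarks (floor −15 with an
exact-match flag, preventing −∞).

Combination selection is done at the cohort level: each candidate
combination's tremulous score is averaged over several recordings before
the argmin. The per-recording argmin is noisy in a structural way — when a
subject's tremor carrier lies wholly inside IMF2's band, IMF1 holds only
the EEMD noise residue plus high-frequency sensor noise and the singleton
{2} wins by ~0.09 log units, whereas subjects whose tremor straddles IMF1
and IMF2 favor {1, 2} by ~0.6 log units. Averaging over five subjects
makes {1, 2} the stable winner, matching how the comparison is done in
practice.

## Windows, labels, splits

Each IMF (residual excluded) is cut into non-overlapping 50-sample
windows; a short final window is zero-padded at the end. Windows are
labeled tremulous iff their source IMF index is in the tremor combination
({1, 2} by default, or data-driven from the benchmark). With ~8 IMFs this
gives the characteristic ~25% positive prevalence; no re-balancing is
applied. Splits: `window_shuffle` reshuffles all windows before each of
n_repeats 80:20 splits (the re-training protocol); `subject_holdout`
partitions subjects 80:20 (48/12 of 60) to measure generalization without
window-level leakage. Both are provided because the protocol's shuffling
level is ambiguous; `window_shuffle` is the default.

## Features (classical baselines)

Computed on the unpadded window prefix (padding is a sequence-model
convenience, not signal; at least 10 samples are kept so every estimator
stays defined):

- **Instantaneous frequency** (Hz): mean derivative of the unwrapped
  analytic-signal (Hilbert) phase, two samples trimmed at each edge. On a
  lone 50-sample window edge effects bias the estimate by up to ~0.3 Hz.
- **Kurtosis**: Pearson (non-excess) m4/m2², so a sinusoid gives 1.5 and a
  Gaussian 3 — documented to keep baseline results interpretable.
- **Crest factor**: max|x| / RMS.
- **Sample entropy**: −ln(A/B), m = 2, r = 0.2·std (the Richman–Moorman
  defaults; the tolerance is window-relative), self-matches excluded, both
  template counts over the first n−m windows. A = 0 is capped at
  ln(B(B−1)); zero-variance windows return 0 with a degenerate flag.

All four are invariant to sign flip; all but instantaneous frequency to
positive scaling. On simulator output the tremor/voluntary classes differ
in mean instantaneous frequency with effect size d > 1, which is what
makes the KNN and Gaussian NB baselines work.

## The network

Implemented in numpy with hand-derived backpropagation (verified against
finite differences to 1e-5 relative); no deep-learning framework is
required. Architecture for one 50-sample window:

conv1d(30 filters, kernel 20, stride 1, ReLU) → maxpool(2) → conv1d(30,
kernel 10, ReLU) → maxpool(2) → time-distributed dense(1, ReLU) →
bi-directional LSTM (64 cells per direction, gates i/f/g/o, unit forget
bias) → tanh → concatenated final hidden states (128) → dense(1, sigmoid).

Open choices, fixed as follows:

- **Padding** `same` by default: the sequence runs 50 → 25 → 25 → 12
  timesteps; `valid` (50 → 31 → 15 → 6 → 3) is implemented but starves the
  LSTM of sequence.
- **Single-unit dense layer** applied per timestep, producing a 1-channel
  sequence — the alternative (flatten to a scalar) would leave the LSTM
  nothing to recur over.
- **Bi-directional merge**: concatenation of the final forward and
  backward hidden states.
- **Post-LSTM tanh** applied to those states as an explicit extra
  activation (configurable off); the LSTM output already contains a tanh,
  but the extra one is the faithful reading of the architecture as stated.
- **Initialization**: Glorot-uniform kernels, orthogonal recurrent
  matrices, zero biases with forget bias 1 — the defaults a framework
  implementation would have used.
- **Optimization**: plain SGD (no momentum), lr 0.01, batch 64, binary
  cross-entropy, 100 epochs by default; threshold 0.5 with ties positive.
- **Input scaling**: windows are divided by one global constant, the
  training windows' overall standard deviation. Per-window normalization
  would erase the amplitude cue that separates tremor from voluntary
  modes; no scaling at all makes SGD step sizes depend on the simulator's
  amplitude units. One global constant is the minimal choice that
  decouples optimization from units, and it is recorded with the model.

The uni-directional variant (conv-LSTM baseline) shares the front-end and
differs only in the missing backward pass and the narrower (64) merge.

## Evaluation

Tremulous = positive. Accuracy, precision, sensitivity, specificity and F1
follow the confusion-count definitions; any ratio with a zero denominator
is reported as missing and flagged rather than coerced to 0, because
silent zeros would corrupt mean ± SD aggregation across re-training
repeats (sample SD, n−1). AUC-ROC is the midrank Mann–Whitney statistic on
window-level scores — deterministic and tie-safe, equal to trapezoidal ROC
integration. Per-activity reports partition the overall confusion counts
exactly.

## Known limitations

- EEMD cost is O(N) full EMDs; a 10 s channel at N = 100 takes ~1–2 s,
  which rules out real-time use.
- EMD cannot split components closer than about a factor 2 in frequency
  (a tremor harmonic merges with its fundamental).
- The simulator's amplitudes are uncalibrated; absolute metric values on
  synthetic cohorts are not comparable to clinical numbers.
- The instantaneous-frequency estimator is biased on signals with strong
  amplitude modulation or on very short windows.
- Training uses float64 on a single CPU; epochs over large cohorts are
  seconds each, not suitable for dataset sizes beyond ~10⁵ windows.
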