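# tremorsep

Separation and classification of Parkinsonian tremor in hand-arm
orientation signals.

Parkinsonian tremor is an involuntary 3–10 Hz oscillation superimposed on
intended (voluntary, < 3 Hz) movement. Wearable orientation sensors record
the two mixed together, and applications such as tremor-compensation
devices need them apart. Fixed band-pass filters struggle because tremor
frequency and amplitude vary across patients and activities. `tremorsep`
implements the adaptive alternative: decompose the raw signal into
intrinsic mode functions (IMFs) with ensemble empirical mode decomposition
(EEMD), then classify fixed-length IMF windows as tremulous or voluntary
with a convolutional bi-directional LSTM — no hand-tuned cut-off
frequencies and no manual feature engineering.

The package is aimed at movement-disorder and biomedical signal-processing
researchers who want a fully testable, self-contained version of this
pipeline: because clinical recordings of this kind are rarely shareable, a
simulator with known ground truth stands in for the data, so every stage —
decomposition quality, benchmark comparison, classification — is
quantifiable.

## The method

**EEMD.** EMD sifts a signal `x(t)` into IMFs: at each step the mean
`m(t)` of the cubic-spline envelopes through the local maxima and minima
is subtracted, `h ← h − m(h)`, until the relative change between sifts

```
D = Σ_t |h_prev(t) − h_curr(t)|² / Σ_t |h_prev(t)|²
```

falls below 0.2 and the candidate satisfies the IMF counting criterion
(numbers of zero crossings and extrema differ by at most one). Each IMF is
removed from the residual and the process repeats until the residual is
monotone. EMD suffers from *mode mixing* — intermittent oscillations share
an IMF with unrelated scales. EEMD decomposes `N` copies of the signal
perturbed with white noise (`std = 0.2·std(x)`, `N = 100`) and averages
IMFs index-wise; the noise populates the spectrum uniformly and cancels at
rate `1/√N`.

**Benchmarking.** A zero-phase 4th-order Butterworth band-pass (3–10 Hz)
and low-pass (3 Hz) provide reference tremulous/voluntary signals. Sums of
IMFs are scored against them with `log10(RMSE)`; the combination of IMF 1
and 2 minimizes the tremulous score on well-behaved recordings and defines
the positive class.

**Classification.** Each IMF is cut into non-overlapping 50-sample windows
(zero-padded at the end), labeled tremulous iff it came from the selected
IMF combination (≈ 25% positives with 8 IMFs), and fed to:

- `conv_bilstm` — conv1d(30 filters, kernel 20, ReLU) → maxpool(2) →
  conv1d(30, kernel 10, ReLU) → maxpool(2) → per-timestep dense(1, ReLU) →
  bi-directional LSTM (64 cells per direction) → tanh → sigmoid unit;
  trained with plain SGD (lr 0.01, batch 64, binary cross-entropy). The
  network is implemented in numpy with manual backpropagation — no deep
  learning framework required.
- `conv_lstm` — the same front-end with a uni-directional LSTM.
- `knn` / `gnb` — 3-nearest-neighbors and Gaussian Naive Bayes on four
  window features: Hilbert instantaneous frequency, kurtosis, crest factor
  (peak/RMS), sample entropy.

Evaluation reports accuracy, precision, sensitivity, specificity, F1 and
rank-based AUC-ROC, aggregated as mean ± SD over shuffled 80:20
re-training repeats.

## Worked example

Five simulated resting recordings (10 s at 100 Hz; tremor carrier drawn
per subject from 3.5–9 Hz), decomposed with EEMD and scored against the
Butterworth benchmarks:

```python
import numpy as np
from tremorsep import (ActivityProfile, generate_cohort, preprocess,
                       eemd, EEMDConfig)
from tremorsep import benchmark as bm

profile = ActivityProfile.default("resting")
recordings, _ = generate_cohort(5, [profile], seed=42)
decomps, cleans = [], []
for rec in recordings:
    clean = preprocess(rec.mixed)
    decomps.append(eemd(clean.values,
                        EEMDConfig(n_ensembles=100, seed=rec.seed)))
    cleans.append(clean)

means, best = bm.score_combinations_cohort(decomps, cleans)
for combo in [(1,), (2,), (1, 2), (2, 3)]:
    print(f"{bm.combo_label(combo):6s} mean tremulous log(RMSE) = "
          f"{means[combo]:+.3f}")
print(f"selected combination: {bm.combo_label(best)}")

corr = np.mean([np.corrcoef(d.imfs[0] + d.imfs[1],
                            r.tremor_truth.values)[0, 1]
                for d, r in zip(decomps, recordings)])
print(f"mean corr(IMF1+IMF2, tremor ground truth) = {corr:.3f}")
```

prints

```
IMF1   mean tremulous log(RMSE) = -0.019
IMF2   mean tremulous log(RMSE) = -0.568
IMF12  mean tremulous log(RMSE) = -0.714
IMF23  mean tremulous log(RMSE) = -0.528
selected combination: IMF12
mean corr(IMF1+IMF2, tremor ground truth) = 0.978
```

The IMF1+IMF2 sum has the lowest (best) average error against the 3–10 Hz
band-pass reference and recovers 97.8% of the tremor ground truth's
structure — single IMFs each capture only part of the tremor, which is why
the combination is scored rather than individual modes.

## Command line

```sh
tremorsep simulate  --out recs --subjects 2 --seed 0
tremorsep decompose recs/recording_0000.csv --out imfs
tremorsep benchmark imfs/recording_0000_imfs.csv recs/recording_0000.csv --out bench
tremorsep run-all   --config config.yaml --out results
```

`run-all` executes simulate → preprocess → EEMD → window/label → train →
evaluate and writes a metrics JSON; all stages are deterministic given the
config seed.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's headline behavior from scratch: it simulates a
five-subject experiment and selects the tremulous IMF combination by
cohort-averaged log(RMSE), then builds a 12-subject × 4-activity cohort,
trains the conv-biLSTM, KNN and Gaussian NB classifiers on labeled IMF
windows over two shuffled 80:20 splits, and evaluates them on held-out
windows (~2–3 min on one CPU). A human-readable run summary is written to
`acceptance_summary.json` beside the requested output file.
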