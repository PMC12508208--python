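"""Windowing, labeling and train/test splitting of IMF decompositions.

Every IMF is cut into non-overlapping windows of 50 samples; a short final
window is zero-padded at the end. Windows from the tremor combination
(IMF 1 and 2 by default, or whichever combination the benchmark selects)
are labeled positive (tremulous), all other IMF windows negative
(voluntary). The residual is excluded. With 8 IMFs per recording and equal
window counts this yields the characteristic 25% positive prevalence.

Splits follow the re-training protocol: the whole window set is shuffled
before each of n_repeats independent 80:20 splits. A subject-holdout mode
(partition at the patient level, e.g. 48/12 of 60) is provided to measure
generalization without window-level leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WINDOW_LEN = 50


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class WindowedSample:
    """A fixed-length IMF segment with label and provenance."""

    values: np.ndarray          # length exactly WINDOW_LEN
    label: int                  # 1 tremulous, 0 voluntary
    recording_id: int
    imf_index: int              # 1-based
    window_index: int
    pad_len: int = 0            # zeros appended (only the final window)
    subject: int = -1
    activity: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        if self.values.size != WINDOW_LEN:
            raise DatasetError(
                f"window length must be {WINDOW_LEN}, got {self.values.size}")
        if not 0 <= self.pad_len < WINDOW_LEN:
            raise DatasetError("pad_len must be in [0, 50)")

    @property
    def unpadded(self) -> np.ndarray:
        """The window without its zero tail (features are computed on this)."""
        return self.values[: WINDOW_LEN - self.pad_len]


@dataclass(frozen=True)
class SplitConfig:
    ratio: float = 0.8
    n_repeats: int = 10
    seed: int = 0
    mode: str = "window_shuffle"  # or "subject_holdout"

    def __post_init__(self):
        if not 0.0 < self.ratio < 1.0:
            raise DatasetError("ratio must be in (0, 1)")
        if self.n_repeats < 1:
            raise DatasetError("n_repeats must be >= 1")
        if self.mode not in ("window_shuffle", "subject_holdout"):
            raise DatasetError(f"unknown split mode {self.mode!r}")


def window_imf(imf: np.ndarray, window: int = WINDOW_LEN,
               recording_id: int = 0, imf_index: int = 1,
               subject: int = -1, activity: str = "") -> list[WindowedSample]:
    """Cut one IMF into ceil(len/window) non-overlapping windows; the last is
    zero-padded at the end if the length is not a multiple of the window."""
    imf = np.asarray(imf, dtype=float)
    if imf.size == 0:
        raise DatasetError("cannot window an empty IMF")
    n_windows = int(np.ceil(imf.size / window))
    out: list[WindowedSample] = []
    for w in range(n_windows):
        seg = imf[w * window: (w + 1) * window]
        pad = window - seg.size
        if pad:
            seg = np.concatenate([seg, np.zeros(pad)])
        out.append(WindowedSample(values=seg, label=0,
                                  recording_id=recording_id,
                                  imf_index=imf_index, window_index=w,
                                  pad_len=pad, subject=subject,
                                  activity=activity))
    return out


def label_windows(samples: list[WindowedSample],
                  tremor_imf_indices: frozenset[int] | set[int] = frozenset({1, 2}),
                  ) -> list[WindowedSample]:
    """Label 1 iff the source IMF index belongs to the tremor combination."""
    tremor_imf_indices = set(tremor_imf_indices)
    out = []
    for s in samples:
        lab = 1 if s.imf_index in tremor_imf_indices else 0
        out.append(WindowedSample(values=s.values, label=lab,
                                  recording_id=s.recording_id,
                                  imf_index=s.imf_index,
                                  window_index=s.window_index,
                                  pad_len=s.pad_len, subject=s.subject,
                                  activity=s.activity))
    return out


def windows_from_decomposition(decomp, recording_id: int = 0,
                               tremor_imf_indices=frozenset({1, 2}),
                               subject: int = -1, activity: str = "",
                               ) -> list[WindowedSample]:
    """Window every IMF of a decomposition (residual excluded) and label."""
    samples: list[WindowedSample] = []
    for k in range(decomp.n_imfs):
        samples.extend(window_imf(decomp.imfs[k], recording_id=recording_id,
                                  imf_index=k + 1, subject=subject,
                                  activity=activity))
    return label_windows(samples, tremor_imf_indices)


def make_splits(samples: list[WindowedSample], cfg: SplitConfig = SplitConfig()
                ) -> list[tuple[list[WindowedSample], list[WindowedSample]]]:
    """n_repeats independent shuffled train/test splits.

    window_shuffle: every window is shuffled and split at the ratio.
    subject_holdout: subjects are partitioned at the ratio; all of a held-out
    subject's windows land in the test set.
    """
    if len(samples) < 10:
        raise DatasetError("need at least 10 samples to split")
    labels = {s.label for s in samples}
    if len(labels) < 2:
        raise DatasetError("dataset contains a single class; cannot split")
    rng = np.random.default_rng(cfg.seed)
    splits = []
    if cfg.mode == "window_shuffle":
        n = len(samples)
        n_train = int(round(cfg.ratio * n))
        for _ in range(cfg.n_repeats):
            perm = rng.permutation(n)
            train = [samples[i] for i in perm[:n_train]]
            test = [samples[i] for i in perm[n_train:]]
            splits.append((train, test))
    else:
        subjects = sorted({s.subject for s in samples})
        if len(subjects) < 2:
            raise DatasetError("subject_holdout needs >= 2 subjects")
        n_train_subj = int(round(cfg.ratio * len(subjects)))
        for _ in range(cfg.n_repeats):
            perm = rng.permutation(len(subjects))
            train_subj = {subjects[i] for i in perm[:n_train_subj]}
            train = [s for s in samples if s.subject in train_subj]
            test = [s for s in samples if s.subject not in train_subj]
            splits.append((train, test))
    return splits


def as_arrays(samples: list[WindowedSample]
              ) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (n, 50) X and (n,) y arrays."""
    X = np.stack([s.values for s in samples])
    y = np.array([s.label for s in samples], dtype=int)
    return X, y
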