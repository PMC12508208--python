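"""Hand-crafted window features for the classical ML baselines.

Four features per window: Hilbert mean instantaneous frequency, Pearson
(non-excess) kurtosis, crest factor (peak magnitude over RMS) and sample
entropy (m=2, r=0.2*std — the Richman-Moorman defaults). Tremor-IMF windows
sit in the 3-10 Hz band and are more regular/tonal; voluntary-IMF windows
are slower and rougher, so instantaneous frequency separates the classes
strongly and the rest refine the boundary.

Features of a zero-padded tail window are computed on the unpadded prefix:
the padding is a sequence-model convenience, not signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

FEATURE_NAMES = ("inst_freq_hz", "kurtosis", "peak_over_rms", "sample_entropy")


@dataclass(frozen=True)
class FeatureVector:
    inst_freq_hz: float
    kurtosis: float
    peak_over_rms: float
    sample_entropy: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.inst_freq_hz, self.kurtosis,
                         self.peak_over_rms, self.sample_entropy])


def instantaneous_frequency(window: np.ndarray, fs: float) -> float:
    """Mean instantaneous frequency (Hz) from the analytic-signal phase.

    The phase of the Hilbert analytic signal is unwrapped, differentiated
    and averaged over the interior (two samples trimmed at each edge where
    the discrete Hilbert transform is least reliable). A constant window
    returns 0.
    """
    x = np.asarray(window, float)
    if x.size < 8:
        raise ValueError("need at least 8 samples for instantaneous frequency")
    if np.ptp(x) == 0:
        return 0.0
    phase = np.unwrap(np.angle(hilbert(x - x.mean())))
    freq = np.diff(phase) * fs / (2.0 * np.pi)
    return float(np.mean(freq[2:-2]))


def kurtosis(window: np.ndarray) -> float:
    """Pearson (non-excess) kurtosis m4 / m2^2; 0 for a zero-variance window."""
    x = np.asarray(window, float)
    x = x - x.mean()
    m2 = np.mean(x ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean(x ** 4) / m2 ** 2)


def peak_to_rms(window: np.ndarray) -> float:
    """Crest factor max|x| / RMS; 0 for an all-zero window."""
    x = np.asarray(window, float)
    rms = np.sqrt(np.mean(x ** 2))
    if rms == 0:
        return 0.0
    return float(np.max(np.abs(x)) / rms)


def sample_entropy(window: np.ndarray, m: int = 2,
                   r_ratio: float = 0.2) -> float:
    """Sample entropy -ln(A/B) in nats.

    B counts template pairs of length m within Chebyshev distance
    r = r_ratio * std(window) (self-matches excluded); A counts pairs of
    length m+1. Both counts run over the first n-m templates so the ratio
    is a conditional probability. A zero-variance window returns 0. If no
    length-(m+1) pair matches (A=0) the infinite estimate is capped at
    ln(B*(B-1)), the standard finite surrogate.
    """
    x = np.asarray(window, float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for sample entropy")
    sd = float(np.std(x))
    if sd == 0:
        return 0.0
    r = r_ratio * sd
    n_templates = n - m
    # Chebyshev distances between all template pairs, vectorized
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templates]
    db = np.max(np.abs(tm[:, None, :] - tm[None, :, :]), axis=2)
    da = np.max(np.abs(tm1[:, None, :] - tm1[None, :, :]), axis=2)
    iu = np.triu_indices(n_templates, k=1)
    b = int(np.sum(db[iu] <= r))
    a = int(np.sum(da[iu] <= r))
    if b == 0:
        return 0.0
    if a == 0:
        return float(np.log(max(b * (b - 1), 2)))
    return float(-np.log(a / b))


def compute_features(window: np.ndarray, fs: float,
                     pad_len: int = 0) -> FeatureVector:
    """Feature vector for one window; padded tails are stripped first."""
    x = np.asarray(window, float)
    if pad_len:
        # keep at least 10 samples so every estimator stays defined
        x = x[: max(x.size - pad_len, 10)]
    degenerate = np.ptp(x) == 0
    return FeatureVector(
        inst_freq_hz=instantaneous_frequency(x, fs),
        kurtosis=kurtosis(x),
        peak_over_rms=peak_to_rms(x),
        sample_entropy=sample_entropy(x),
        degenerate=bool(degenerate),
    )


def feature_matrix(samples, fs: float) -> np.ndarray:
    """(n, 4) feature matrix for a list of WindowedSample."""
    return np.stack([compute_features(s.values, fs, s.pad_len).as_array()
                     for s in samples])
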