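"""Empirical mode decomposition and its noise-assisted ensemble variant.

EMD sifts a signal into intrinsic mode functions (IMFs): starting from the
signal, the mean of the cubic-spline envelopes through the local maxima and
minima is subtracted repeatedly (h <- h - m(h)) until the relative squared
change between consecutive sifts,

    D = sum |h_prev - h_curr|^2 / sum |h_prev|^2,

falls below a threshold (default 0.2, the standard Cauchy-type criterion).
The extracted IMF is removed from the running residual and the process
repeats until the residual is monotone (fewer than two maxima or minima) or
a maximum IMF count is reached. By construction the IMFs and the residual
telescope back to the input exactly.

EMD suffers from mode mixing: oscillations of different scales can land in
one IMF when a component is intermittent. Ensemble EMD (EEMD) mitigates
this by decomposing many white-noise-perturbed copies of the signal and
averaging the IMFs index-wise; the noise populates the full spectrum so
each sift separates scales consistently, and it cancels in the ensemble
mean at rate 1/sqrt(N).

Envelope boundaries are handled by mirroring the two nearest extrema about
each endpoint, the common guard against edge swing; splines are natural
cubic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline


class DecompositionError(ValueError):
    pass


class InsufficientExtremaError(DecompositionError):
    """Signal is monotone (or nearly): fewer than 2 maxima or 2 minima."""


@dataclass(frozen=True)
class EMDConfig:
    stoppage_threshold: float = 0.2
    max_siftings: int = 50
    max_imfs: int = 12
    min_extrema: int = 2

    def __post_init__(self):
        if (self.stoppage_threshold <= 0 or self.max_siftings <= 0
                or self.max_imfs <= 0 or self.min_extrema <= 0):
            raise ValueError("all EMDConfig fields must be positive")


@dataclass(frozen=True)
class EEMDConfig:
    emd: EMDConfig = field(default_factory=EMDConfig)
    n_ensembles: int = 100
    noise_std_ratio: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_ensembles < 1:
            raise ValueError("n_ensembles must be >= 1")
        if self.noise_std_ratio < 0:
            raise ValueError("noise_std_ratio must be >= 0")


@dataclass(frozen=True)
class IMFDecomposition:
    """Ordered IMFs plus residual for one signal.

    ``imfs`` is a (K, n) array, IMF 1 in row 0. For plain EMD,
    sum(imfs) + residual reproduces the input to machine precision.
    """

    imfs: np.ndarray
    residual: np.ndarray
    method: str  # "EMD" | "EEMD"
    config: EMDConfig | EEMDConfig

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def imf(self, index: int) -> np.ndarray:
        """1-based IMF accessor (IMF 1 is the fastest mode)."""
        if not 1 <= index <= self.n_imfs:
            raise IndexError(f"IMF index {index} out of range 1..{self.n_imfs}")
        return self.imfs[index - 1]

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima by three-point comparison.

    A flat plateau that is a local extremum contributes its midpoint once;
    monotone and constant signals have no extrema. Endpoints are never
    extrema.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    dx = np.diff(x)
    nz = np.nonzero(dx)[0]
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    signs = np.sign(dx[nz])
    maxima, minima = [], []
    for k in range(signs.size - 1):
        if signs[k] > 0 and signs[k + 1] < 0:
            # plateau (possibly width 1) between nz[k]+1 and nz[k+1]
            maxima.append((nz[k] + 1 + nz[k + 1]) // 2)
        elif signs[k] < 0 and signs[k + 1] > 0:
            minima.append((nz[k] + 1 + nz[k + 1]) // 2)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x[x != 0])
    if s.size < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))


def _mirrored_spline(t: np.ndarray, v: np.ndarray, n: int) -> np.ndarray:
    """Natural cubic spline through (t, v), with the two nearest extrema
    mirrored about each endpoint (t=0 and t=n-1) to tame edge swing."""
    k = min(2, t.size)
    left_t = (-t[:k])[::-1]
    left_v = (v[:k])[::-1]
    right_t = (2 * (n - 1) - t[-k:])[::-1]
    right_v = (v[-k:])[::-1]
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    tt, keep = np.unique(tt, return_index=True)
    vv = vv[keep]
    if tt.size < 2:
        raise InsufficientExtremaError("not enough envelope knots")
    if tt.size < 4:  # CubicSpline needs >= 2 pts; fall back to lower order
        from scipy.interpolate import interp1d
        kind = "linear" if tt.size == 2 else "quadratic"
        return interp1d(tt, vv, kind=kind, fill_value="extrapolate")(np.arange(n))
    return CubicSpline(tt, vv, bc_type="natural")(np.arange(n))


def envelope_mean(x: np.ndarray,
                  maxima: np.ndarray,
                  minima: np.ndarray) -> np.ndarray:
    """Pointwise mean of the upper (through maxima) and lower (through
    minima) cubic-spline envelopes. Raises
    :class:`InsufficientExtremaError` with fewer than 2 of either kind."""
    x = np.asarray(x, dtype=float)
    if maxima.size < 2 or minima.size < 2:
        raise InsufficientExtremaError(
            f"need >= 2 maxima and minima, got {maxima.size}/{minima.size}")
    upper = _mirrored_spline(np.asarray(maxima, float), x[maxima], x.size)
    lower = _mirrored_spline(np.asarray(minima, float), x[minima], x.size)
    return 0.5 * (upper + lower)


def stoppage_criterion(h_prev: np.ndarray, h_curr: np.ndarray) -> float:
    """Relative squared change between consecutive sifts."""
    h_prev = np.asarray(h_prev, float)
    h_curr = np.asarray(h_curr, float)
    if h_prev.shape != h_curr.shape:
        raise DecompositionError("h_prev and h_curr must have equal length")
    denom = float(np.sum(h_prev ** 2))
    if denom == 0.0:
        raise DecompositionError("stoppage criterion undefined for "
                                 "zero-energy h_prev")
    return float(np.sum((h_prev - h_curr) ** 2)) / denom


def _imf_count_criterion(h: np.ndarray, maxima: np.ndarray,
                         minima: np.ndarray) -> bool:
    """IMF counting criterion: zero crossings and extrema differ by <= 1."""
    return abs((maxima.size + minima.size) - count_zero_crossings(h)) <= 1


def sift_one_imf(x: np.ndarray, cfg: EMDConfig = EMDConfig()
                 ) -> tuple[np.ndarray, int]:
    """Extract one IMF: iterate h <- h - m(h) until the stoppage criterion
    drops below threshold AND the candidate satisfies the IMF counting
    criterion (zero crossings and extrema differ by at most one), or
    ``max_siftings`` is reached.

    Returns (imf, number of sifts). Raises
    :class:`InsufficientExtremaError` if the input itself lacks extrema.
    """
    h = np.asarray(x, dtype=float).copy()
    maxima, minima = find_extrema(h)
    if maxima.size < cfg.min_extrema or minima.size < cfg.min_extrema:
        raise InsufficientExtremaError("monotone residual reached")
    n_sifts = 0
    for _ in range(cfg.max_siftings):
        try:
            m = envelope_mean(h, maxima, minima)
        except InsufficientExtremaError:
            break
        h_new = h - m
        n_sifts += 1
        d = stoppage_criterion(h, h_new)
        h = h_new
        maxima, minima = find_extrema(h)
        if maxima.size < cfg.min_extrema or minima.size < cfg.min_extrema:
            break
        if d < cfg.stoppage_threshold and _imf_count_criterion(h, maxima,
                                                               minima):
            break
    return h, n_sifts


def emd(x: np.ndarray, cfg: EMDConfig = EMDConfig()) -> IMFDecomposition:
    """Full EMD: repeatedly sift IMFs out of the running residual until it
    is monotone or ``max_imfs`` is reached.

    Completeness is exact by telescoping: sum(IMFs) + residual == input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise DecompositionError("signal too short for EMD (need >= 10 samples)")
    if np.isnan(x).any():
        raise DecompositionError("signal contains missing values; preprocess first")
    residual = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < cfg.max_imfs:
        try:
            imf, _ = sift_one_imf(residual, cfg)
        except InsufficientExtremaError:
            break
        imfs.append(imf)
        residual = residual - imf
    imf_arr = (np.vstack(imfs) if imfs
               else np.empty((0, x.size), dtype=float))
    return IMFDecomposition(imfs=imf_arr, residual=residual,
                            method="EMD", config=cfg)


def eemd(x: np.ndarray, cfg: EEMDConfig = EEMDConfig()) -> IMFDecomposition:
    """Ensemble EMD: average EMD decompositions of N noise-perturbed copies.

    Member n decomposes x + w_n where w_n is white Gaussian noise with
    std = noise_std_ratio * std(x), drawn from seed + n. IMFs are aligned by
    index and zero-padded to the ensemble-wide maximum count before
    averaging; residuals are averaged likewise. With noise_std_ratio=0 and
    one member this reduces bitwise to plain EMD.
    """
    x = np.asarray(x, dtype=float)
    noise_std = cfg.noise_std_ratio * float(np.std(x))
    member_imfs: list[np.ndarray] = []
    member_res: list[np.ndarray] = []
    for n in range(1, cfg.n_ensembles + 1):
        if noise_std > 0:
            rng = np.random.default_rng(cfg.seed + n)
            xn = x + rng.standard_normal(x.size) * noise_std
        else:
            xn = x
        dec = emd(xn, cfg.emd)
        member_imfs.append(dec.imfs)
        member_res.append(dec.residual)
    k_max = max(m.shape[0] for m in member_imfs)
    total = np.zeros((k_max, x.size), dtype=float)
    for m in member_imfs:
        total[: m.shape[0]] += m
    mean_imfs = total / cfg.n_ensembles
    mean_res = np.mean(member_res, axis=0)
    return IMFDecomposition(imfs=mean_imfs, residual=mean_res,
                            method="EEMD", config=cfg)
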