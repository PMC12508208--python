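"""Preprocessing: PCHIP interpolation of missing samples and linear detrend.

Interpolation runs first (detrending needs complete data). Missing samples
are NaN; endpoints must be present — the shape-preserving piecewise cubic
Hermite interpolant is only ever evaluated between present samples, never
extrapolated.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from .signal import OrientationSignal


class PreprocessingError(ValueError):
    pass


def interpolate_missing(signal: OrientationSignal) -> OrientationSignal:
    """Fill NaN samples with a shape-preserving piecewise cubic Hermite
    interpolant through the present samples.

    Present samples are returned unchanged; a complete signal comes back
    identical. Raises :class:`PreprocessingError` if an endpoint is missing
    (no extrapolation) or fewer than 2 samples are present.
    """
    x = signal.values
    missing = np.isnan(x)
    if not missing.any():
        return signal
    if missing[0] or missing[-1]:
        raise PreprocessingError(
            "cannot interpolate a missing endpoint (no extrapolation)")
    present = ~missing
    if present.sum() < 2:
        raise PreprocessingError("need at least 2 present samples")
    idx = np.arange(x.size)
    interp = PchipInterpolator(idx[present], x[present])
    out = x.copy()
    out[missing] = interp(idx[missing])
    return signal.with_values(out)


def detrend_linear(signal: OrientationSignal) -> OrientationSignal:
    """Subtract the ordinary-least-squares straight line from the signal.

    The output has zero mean and zero least-squares slope. Requires a
    complete signal (interpolate first).
    """
    x = signal.values
    if x.size < 2:
        raise PreprocessingError("need at least 2 samples to detrend")
    if np.isnan(x).any():
        raise PreprocessingError("detrend requires a complete signal; "
                                 "interpolate missing samples first")
    return signal.with_values(sps.detrend(x, type="linear"))


def preprocess(signal: OrientationSignal) -> OrientationSignal:
    """Interpolate missing samples, then remove the linear trend."""
    return detrend_linear(interpolate_missing(signal))
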