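"""Shared band-pass filter used by the analysis and the signal generator.

Using one filter implementation on both sides guarantees that the analysis
filter cannot distort correlation structure planted by the synthetic
generator: band-limited synthesis and band-pass cleaning commute.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

DEFAULT_BAND = (0.009, 0.08)  # Hz


def validate_band(band: tuple[float, float], tr: float) -> None:
    low, high = band
    nyquist = 1.0 / (2.0 * tr)
    if not (0.0 < low < high < nyquist):
        raise ValueError(
            f"band {band} must satisfy 0 < low < high < Nyquist ({nyquist:.4g} Hz "
            f"at tr={tr} s)"
        )


def bandpass_filter(
    x: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    tr: float = 0.8,
    order: int = 4,
    detrend: bool = True,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0.

    Applies a linear detrend followed by a forward-backward (zero-phase)
    Butterworth band-pass. The same operator must be applied to data and
    nuisance regressors so that regression happens in a common spectral
    space.

    Parameters
    ----------
    x : array, shape (T,) or (T, m)
        Input series, time on axis 0.
    band : (low, high) in Hz.
    tr : sampling interval in seconds.
    order : Butterworth section order (doubled by the two-pass application).
    detrend : remove a per-column linear trend first.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input series")
    validate_band(band, tr)
    fs = 1.0 / tr
    if detrend:
        x = sps.detrend(x, axis=0, type="linear")
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)
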