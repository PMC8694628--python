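"""Band-pass filtering, resampling, and feature normalization.

Offline analysis uses third-order Butterworth band-pass filters applied
forward-backward (zero phase), with per-modality default bands:
SCG 4-24 Hz, ECG 0.5-50 Hz, PPG 0.3-7 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandSpec",
    "SCG_BAND",
    "ECG_BAND",
    "PPG_BAND",
    "SCG_WIDE_BAND",
    "bandpass",
    "resample",
    "min_max_normalize",
]


@dataclass(frozen=True)
class BandSpec:
    lo: float
    hi: float
    order: int = 3

    def validate(self, rate: float) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError("band must satisfy 0 < lo < hi")
        if self.hi >= rate / 2:
            raise ValueError(f"band hi {self.hi} Hz >= Nyquist {rate / 2} Hz")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


SCG_BAND = BandSpec(4.0, 24.0)
ECG_BAND = BandSpec(0.5, 50.0)
PPG_BAND = BandSpec(0.3, 7.0)
#: widened SCG band used for the apnea scalograms (respiratory content kept)
SCG_WIDE_BAND = BandSpec(0.1, 24.0)


def bandpass(
    x: np.ndarray, rate: float, band: BandSpec, zero_phase: bool = True
) -> np.ndarray:
    """Butterworth band-pass; zero-phase (filtfilt) by default."""
    band.validate(rate)
    x = np.asarray(x, dtype=float)
    sos = sps.butter(band.order, [band.lo, band.hi], btype="bandpass", fs=rate, output="sos")
    if zero_phase:
        padlen = min(x.size - 1, 3 * int(rate / band.lo))
        return sps.sosfiltfilt(sos, x, padlen=padlen)
    return sps.sosfilt(sos, x)


def resample(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Band-limited (polyphase) resampling preserving duration."""
    if rate_in <= 0 or rate_out <= 0:
        raise ValueError("rates must be positive")
    x = np.asarray(x, dtype=float)
    if rate_in == rate_out:
        return x.copy()
    from fractions import Fraction

    frac = Fraction(rate_out / rate_in).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def min_max_normalize(
    features: np.ndarray, params: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Column-wise min-max scaling to [0, 1].

    When `params` (mins, maxs) is given it is re-applied (values may then
    fall outside [0, 1]); otherwise the params are fitted.  A zero-range
    column is mapped to 0.5 with a warning.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    if params is None:
        if x.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit normalization params")
        mins = np.nanmin(x, axis=0)
        maxs = np.nanmax(x, axis=0)
    else:
        mins, maxs = params
    span = maxs - mins
    degenerate = span <= 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} constant feature column(s) mapped to 0.5",
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, span)
    out = (x - mins) / safe
    out[:, degenerate] = 0.5
    return out, (mins, maxs)
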