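"""Reflectance pulse oximetry: ratio-of-ratios SpO2 estimation.

The pulsatile (AC) and baseline (DC) components of the red and infrared
PPG channels give the perfusion ratio R = (AC_red/DC_red)/(AC_ir/DC_ir),
which maps to oxygen saturation through a linear calibration
SpO2 = a - b*R.  Because the sternal PPG leads a peripheral (finger)
measurement, the series can be delayed by the central-to-peripheral
transport delay (10 s) for comparison with reference devices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import PPG_BAND, BandSpec, bandpass

__all__ = [
    "SpO2Series",
    "ac_dc_decompose",
    "ratio_of_ratios",
    "spo2_from_ratio",
    "align_central",
    "spo2_series",
    "DEFAULT_CALIB",
]

#: conventional uncalibrated reflectance line SpO2 = 110 - 25 R (config-overridable)
DEFAULT_CALIB = (110.0, 25.0)


@dataclass
class SpO2Series:
    times: np.ndarray
    spo2: np.ndarray
    r_values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        ok = self.valid
        if np.any((self.spo2[ok] < 0) | (self.spo2[ok] > 100)):
            raise ValueError("valid SpO2 outside [0, 100]")


def ac_dc_decompose(
    ppg: np.ndarray, rate: float, window: float = 4.0, overlap: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Windowed pulsatile amplitude and baseline level of one PPG channel.

    DC is the mean of the sub-0.3-Hz trend per window; AC is the
    peak-to-trough amplitude of the 0.3-7-Hz pulsatile component.
    Windows whose DC is non-positive are flagged invalid.
    Returns (window center times, ac, dc, valid).
    """
    x = np.asarray(ppg, dtype=float)
    pulsatile = bandpass(x, rate, PPG_BAND)
    trend = x - bandpass(x, rate, BandSpec(0.3, min(7.0, rate / 2.5), 3))
    step = window * (1.0 - overlap)
    n_win = int(np.floor((x.size / rate - window) / step)) + 1
    if n_win < 1:
        z = np.array([])
        return z, z, z, np.array([], dtype=bool)
    t0s = np.arange(n_win) * step
    ac = np.empty(n_win)
    dc = np.empty(n_win)
    for i, t0 in enumerate(t0s):
        j0 = int(round(t0 * rate))
        j1 = j0 + int(round(window * rate))
        seg = pulsatile[j0:j1]
        ac[i] = float(seg.max() - seg.min())
        dc[i] = float(trend[j0:j1].mean())
    valid = dc > 0
    return t0s + window / 2, ac, dc, valid


def ratio_of_ratios(
    ac_r: np.ndarray, dc_r: np.ndarray, ac_ir: np.ndarray, dc_ir: np.ndarray
) -> np.ndarray:
    """R = (AC_red/DC_red) / (AC_ir/DC_ir); NaN where any input is <= 0."""
    arrs = [np.asarray(a, dtype=float) for a in (ac_r, dc_r, ac_ir, dc_ir)]
    ok = np.all([a > 0 for a in arrs], axis=0)
    out = np.full(arrs[0].shape, np.nan)
    a, b, c, d = arrs
    out[ok] = (a[ok] / b[ok]) / (c[ok] / d[ok])
    return out


def spo2_from_ratio(
    r: np.ndarray, calib: tuple[float, float] = DEFAULT_CALIB
) -> np.ndarray:
    """SpO2 (%) from the perfusion ratio via the linear calibration,
    clipped to [0, 100]."""
    a, b = calib
    return np.clip(a - b * np.asarray(r, dtype=float), 0.0, 100.0)


def align_central(series: SpO2Series, delay: float = 10.0) -> SpO2Series:
    """Shift the time axis by +delay seconds (central-to-peripheral
    alignment); no resampling."""
    return replace(series, times=series.times + delay)


def spo2_series(
    ppg_red: np.ndarray,
    ppg_ir: np.ndarray,
    rate: float,
    calib: tuple[float, float] = DEFAULT_CALIB,
    window: float = 4.0,
) -> SpO2Series:
    """Full pipeline: AC/DC decomposition of both channels -> R -> SpO2."""
    t, ac_r, dc_r, ok_r = ac_dc_decompose(ppg_red, rate, window)
    _, ac_i, dc_i, ok_i = ac_dc_decompose(ppg_ir, rate, window)
    r = ratio_of_ratios(ac_r, dc_r, ac_i, dc_i)
    valid = ok_r & ok_i & np.isfinite(r)
    spo2 = np.where(valid, spo2_from_ratio(np.where(valid, r, 1.0), calib), np.nan)
    return SpO2Series(times=t, spo2=spo2, r_values=r, valid=valid)
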