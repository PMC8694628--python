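"""Respiration and body position from the 3-axis accelerometer.

Tidal chest motion appears as a 0.1-0.7 Hz oscillation on the
dorso-ventral axis; its envelope is the respiratory effort (RE, in g) and
its dominant spectral frequency the respiration rate (RR).  The low-passed
gravity vector gives body position: with the device z-axis pointing out of
the chest, supine means gravity along -z; the transverse-plane angle is
quantized into four quadrants (supine / left / prone / right).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import BandSpec, bandpass

__all__ = [
    "respiratory_effort",
    "respiration_rate",
    "body_position",
    "POSITIONS",
]

RESP_BAND = BandSpec(0.1, 0.7, 3)
POSITIONS = ("supine", "left", "prone", "right")


def respiratory_effort(
    acc_z: np.ndarray, rate: float, window: float = 10.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Respiratory-effort series and the band-passed waveform.

    The dorso-ventral axis is filtered to 0.1-0.7 Hz; RE per 10-s window is
    the mean analytic-envelope amplitude (g).  Returns (series with columns
    time/re, waveform) — the waveform is emitted for plotting and for the
    rate estimator.
    """
    wave = bandpass(np.asarray(acc_z, dtype=float), rate, RESP_BAND)
    env = np.abs(sps.hilbert(wave))
    n_win = int(np.floor(wave.size / rate / window))
    rows = []
    for i in range(n_win):
        j0 = int(i * window * rate)
        j1 = int((i + 1) * window * rate)
        rows.append((i * window + window / 2, float(env[j0:j1].mean())))
    return pd.DataFrame(rows, columns=["time", "re"]), wave


def respiration_rate(
    re_waveform: np.ndarray,
    rate: float,
    window: float = 60.0,
    step: float | None = None,
    min_power_frac: float = 0.05,
) -> pd.DataFrame:
    """Respiration rate (breaths/min) from the dominant 0.1-0.7 Hz peak.

    Per window, the zero-padded spectrum of the respiratory waveform is
    searched in-band and the peak refined by parabolic interpolation;
    windows whose in-band RMS falls below ``min_power_frac`` of the
    record-wide median RMS are flagged missing (NaN) — a flat apnea window
    carries no rate.
    """
    x = np.asarray(re_waveform, dtype=float)
    step = step or window
    n_win = int(np.floor((x.size / rate - window) / step)) + 1
    if n_win < 1:
        return pd.DataFrame(columns=["time", "rr"])
    nseg = int(window * rate)
    rms_all = [
        np.sqrt(np.mean(x[int(i * step * rate) : int(i * step * rate) + nseg] ** 2))
        for i in range(n_win)
    ]
    floor_rms = min_power_frac * max(np.median(rms_all), 1e-12)
    rows = []
    nfft = int(2 ** np.ceil(np.log2(nseg * 8)))
    freqs = np.fft.rfftfreq(nfft, 1.0 / rate)
    band = (freqs >= RESP_BAND.lo) & (freqs <= RESP_BAND.hi)
    for i in range(n_win):
        t0 = i * step
        seg = x[int(t0 * rate) : int(t0 * rate) + nseg]
        if rms_all[i] < floor_rms:
            rows.append((t0 + window / 2, np.nan))
            continue
        spec = np.abs(np.fft.rfft(seg * np.hanning(seg.size), nfft))
        idx = np.flatnonzero(band)
        k = idx[np.argmax(spec[idx])]
        # parabolic refinement
        if 0 < k < freqs.size - 1 and spec[k] > 0:
            ym, y0, yp = spec[k - 1], spec[k], spec[k + 1]
            denom = ym - 2 * y0 + yp
            off = 0.5 * (ym - yp) / denom if denom < 0 else 0.0
        else:
            off = 0.0
        f_hat = freqs[k] + off * (freqs[1] - freqs[0])
        rows.append((t0 + window / 2, 60.0 * f_hat))
    return pd.DataFrame(rows, columns=["time", "rr"])


def body_position(
    acc: np.ndarray, rate: float, window: float = 10.0, g_tol: float = 0.3
) -> pd.DataFrame:
    """Quadrant body-position labels from the low-passed gravity vector.

    `acc` is (3, n) in g.  Per window the sub-0.1-Hz gravity vector is
    averaged; its angle in the transverse (mediolateral y, dorsoventral z)
    plane — theta = atan2(g_y, -g_z), so supine is 0 and left +90 deg — is
    quantized into counterclockwise-closed quadrants [theta0 - 45,
    theta0 + 45).  Windows where | |g| - 1 | exceeds `g_tol` are labelled
    ``moving``.
    """
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[0] != 3:
        raise ValueError("acc must be (3, n)")
    sos = sps.butter(2, 0.1, btype="lowpass", fs=rate, output="sos")
    grav = np.vstack([sps.sosfiltfilt(sos, acc[i]) for i in range(3)])
    n_win = int(np.floor(acc.shape[1] / rate / window))
    rows = []
    for i in range(n_win):
        j0, j1 = int(i * window * rate), int((i + 1) * window * rate)
        g = grav[:, j0:j1].mean(axis=1)
        mag = float(np.linalg.norm(g))
        if abs(mag - 1.0) > g_tol:
            rows.append((i * window, "moving"))
            continue
        theta = np.degrees(np.arctan2(g[1], -g[2])) % 360.0
        # quadrants closed on their counterclockwise start: [315,45)->supine,
        # [45,135)->left, [135,225)->prone, [225,315)->right
        q = int(((theta + 45.0) % 360.0) // 90.0)
        rows.append((i * window, POSITIONS[q]))
    return pd.DataFrame(rows, columns=["time", "position"])
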