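"""ECG beat detection and seismocardiogram timing analysis.

R peaks are found with a derivative-energy detection function of the
Pan-Tompkins family (squared derivative, moving-window integration,
adaptive threshold, 200-ms refractory).  SCG beats segmented at the R peaks
are ensemble-averaged and the aortic-opening (AO), aortic-closure-movement
(ACM) and aortic-closure (AC) fiducials are picked inside configurable
search windows, yielding the systolic-timing intervals PEP (R to AO) and
LVET (AO to AC) and the AO magnitude |AO|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import BandSpec, bandpass

__all__ = [
    "BeatTable",
    "ScgEnsemble",
    "FiducialSet",
    "detect_r_peaks",
    "hr_hrv_series",
    "segment_and_ensemble",
    "detect_fiducials",
    "kinetic_energy_bands",
    "KE_BANDS",
]

KE_BANDS = ((20.0, 25.0), (25.0, 30.0), (30.0, 35.0), (35.0, 40.0))


@dataclass
class BeatTable:
    """Detected R-peak times (s), with per-beat template-correlation quality."""

    r_times: np.ndarray
    quality: np.ndarray
    low_quality: bool = False

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        if self.r_times.size != self.quality.size:
            raise ValueError("r_times and quality lengths differ")
        if np.any(np.diff(self.r_times) <= 0.2):
            raise ValueError("RR intervals must exceed the 200-ms refractory")

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.r_times)

    def __len__(self) -> int:
        return self.r_times.size


@dataclass
class ScgEnsemble:
    """R-aligned beat matrix and its ensemble average."""

    matrix: np.ndarray  # beats x samples
    rate: float
    window: float
    beat_times: np.ndarray

    @property
    def average(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    @property
    def beat_count(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FiducialSet:
    """Fiducial times (s after R) and derived systolic intervals."""

    ao: float | None
    acm: float | None
    ac: float | None
    ao_mag: float | None
    flags: list[str] = field(default_factory=list)

    @property
    def pep(self) -> float | None:
        """Pre-ejection period proxy, ms (R to AO)."""
        return None if self.ao is None else self.ao * 1000.0

    @property
    def lvet(self) -> float | None:
        """Left-ventricular ejection time, ms (AO to AC)."""
        if self.ao is None or self.ac is None:
            return None
        return (self.ac - self.ao) * 1000.0


def detect_r_peaks(ecg: np.ndarray, rate: float) -> BeatTable:
    """Adaptive-threshold R-peak detection on a band-passed ECG.

    A flatline or feature-free input yields an empty table flagged
    ``low_quality`` rather than an exception.
    """
    x = np.asarray(ecg, dtype=float)
    if x.size < int(rate):
        return BeatTable(np.array([]), np.array([]), low_quality=True)
    scale = np.percentile(np.abs(x), 99)
    if scale <= 1e-12:  # flatline
        return BeatTable(np.array([]), np.array([]), low_quality=True)
    xn = x / scale
    # QRS enhancement: the R complex lives in ~5-22 Hz; narrowing before
    # differentiation keeps wideband noise out of the detection function
    qrs = bandpass(xn, rate, BandSpec(5.0, min(22.0, 0.45 * rate), 2))
    det = np.gradient(qrs) ** 2
    win = max(1, int(0.15 * rate))
    det = np.convolve(det, np.ones(win) / win, mode="same")
    # adaptive height: 20 % of the 98th percentile within 10-s blocks
    block = max(1, int(10 * rate))
    thr = np.empty_like(det)
    for i in range(0, det.size, block):
        seg = det[i : i + block]
        thr[i : i + block] = 0.2 * np.percentile(seg, 98)
    cand, _ = sps.find_peaks(det, distance=int(0.2 * rate) + 1)
    cand = cand[det[cand] > np.maximum(thr[cand], 1e-6)]
    if cand.size == 0:
        return BeatTable(np.array([]), np.array([]), low_quality=True)
    # refine to the local ECG maximum (R wave) near each detection
    half = int(0.06 * rate)
    peaks = []
    for c in cand:
        j0, j1 = max(0, c - half), min(x.size, c + half + 1)
        peaks.append(j0 + int(np.argmax(xn[j0:j1])))
    peaks = np.array(sorted(set(peaks)))
    keep = np.concatenate([[True], np.diff(peaks) > 0.2 * rate])
    peaks = peaks[keep]
    r_times = peaks / rate
    quality = _template_quality(xn, peaks, rate)
    return BeatTable(r_times, quality)


def _template_quality(x: np.ndarray, peaks: np.ndarray, rate: float) -> np.ndarray:
    half = int(0.15 * rate)
    segs = []
    for p in peaks:
        if p - half < 0 or p + half >= x.size:
            segs.append(None)
        else:
            segs.append(x[p - half : p + half])
    good = [s for s in segs if s is not None]
    if len(good) < 2:
        return np.ones(peaks.size)
    template = np.mean(good, axis=0)
    tz = template - template.mean()
    tn = np.linalg.norm(tz) or 1.0
    out = np.ones(peaks.size)
    for i, s in enumerate(segs):
        if s is None:
            out[i] = 0.5
            continue
        sz = s - s.mean()
        denom = (np.linalg.norm(sz) * tn) or 1.0
        out[i] = float(np.clip(np.dot(sz, tz) / denom, 0.0, 1.0))
    return out


def hr_hrv_series(
    beats: BeatTable, window: float = 30.0, step: float = 30.0
) -> pd.DataFrame:
    """Windowed HR (60/mean RR), SDNN and RMSSD series.

    Windows with fewer than 2 beats emit NaN rows (missing markers).
    Returned times are window centers.
    """
    if len(beats) == 0:
        return pd.DataFrame(columns=["time", "hr", "sdnn", "rmssd"])
    t_end = beats.r_times[-1]
    starts = np.arange(0.0, max(t_end - window, 0.0) + step / 2, step)
    rows = []
    for t0 in starts:
        sel = (beats.r_times >= t0) & (beats.r_times < t0 + window)
        rr = np.diff(beats.r_times[sel])
        if rr.size < 1:
            rows.append((t0 + window / 2, np.nan, np.nan, np.nan))
            continue
        hr = 60.0 / rr.mean()
        sdnn = 1000.0 * rr.std(ddof=1) if rr.size > 1 else 0.0
        drr = np.diff(rr)
        rmssd = 1000.0 * np.sqrt(np.mean(drr**2)) if drr.size else np.nan
        rows.append((t0 + window / 2, hr, sdnn, rmssd))
    return pd.DataFrame(rows, columns=["time", "hr", "sdnn", "rmssd"])


def segment_and_ensemble(
    scg: np.ndarray,
    rate: float,
    beats: BeatTable,
    window: float = 0.5,
    quality_threshold: float = 0.5,
) -> ScgEnsemble:
    """Cut [R, R+window) beats from the band-passed SCG and average them.

    Beats below the quality threshold, or running off the end of the
    signal, are excluded.
    """
    if len(beats) == 0:
        raise ValueError("no beats to segment")
    n = int(round(window * rate))
    rows, used = [], []
    for t0, q in zip(beats.r_times, beats.quality):
        if q < quality_threshold:
            continue
        j0 = int(round(t0 * rate))
        if j0 + n > scg.size:
            continue
        rows.append(scg[j0 : j0 + n])
        used.append(t0)
    if not rows:
        raise ValueError("all beats excluded")
    return ScgEnsemble(np.vstack(rows), rate, window, np.array(used))


def detect_fiducials(
    ens: ScgEnsemble,
    ao_window: tuple[float, float] = (0.02, 0.15),
    ac_window: tuple[float, float] = (0.25, 0.45),
    ao_mag_mode: str = "envelope",
) -> FiducialSet:
    """Pick AO/ACM/AC on the ensemble-average beat.

    AO is the largest positive peak in the S1 window, AC the largest
    positive peak in the S2 window, and ACM the last local peak between AO
    and 10 ms before AC.  |AO| is the analytic-envelope magnitude at AO
    (``ao_mag_mode='raw'`` returns the raw sample instead).  An empty
    search window flags the fiducial as missing rather than fabricating it.
    """
    avg = ens.average
    rate = ens.rate
    t = np.arange(avg.size) / rate
    flags: list[str] = []

    def _window_peak(lo: float, hi: float) -> float | None:
        sel = (t >= lo) & (t < hi)
        if not np.any(sel):
            return None
        idx = np.flatnonzero(sel)
        return float(t[idx[np.argmax(avg[idx])]])

    ao = _window_peak(*ao_window)
    if ao is None:
        flags.append("ao_missing")
    ac = _window_peak(*ac_window)
    if ac is None:
        flags.append("ac_missing")
    acm = None
    if ao is not None and ac is not None:
        lo = max(ac_window[0], ao + 0.02)
        sel = (t >= lo) & (t < ac - 0.01)
        idx = np.flatnonzero(sel)
        if idx.size >= 3:
            local = sps.argrelmax(avg[idx])[0]
            if local.size:
                acm = float(t[idx[local[-1]]])
        if acm is None:
            flags.append("acm_missing")
    ao_mag = None
    if ao is not None:
        j = int(round(ao * rate))
        if ao_mag_mode == "envelope":
            ao_mag = float(np.abs(sps.hilbert(avg))[j])
        else:
            ao_mag = float(abs(avg[j]))
    return FiducialSet(ao=ao, acm=acm, ac=ac, ao_mag=ao_mag, flags=flags)


def kinetic_energy_bands(
    scg: np.ndarray,
    rate: float,
    bands: tuple[tuple[float, float], ...] = KE_BANDS,
    window: float = 5.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Band-limited cardiac kinetic-energy features.

    For each 5-s window (50 % overlap, so starts every 2.5 s) and each
    frequency band, the mean magnitude of the analytic (Hilbert) signal of
    the band-filtered SCG.  Returns (window start times, features matrix).
    """
    if rate <= 80:
        raise ValueError("kinetic-energy bands need rate > 80 Hz")
    x = np.asarray(scg, dtype=float)
    step = window * (1.0 - overlap)
    n_win = int(np.floor((x.size / rate - window) / step)) + 1
    if n_win < 1:
        return np.array([]), np.zeros((0, len(bands)))
    starts = np.arange(n_win) * step
    feats = np.empty((n_win, len(bands)))
    for bi, (lo, hi) in enumerate(bands):
        env = np.abs(sps.hilbert(bandpass(x, rate, BandSpec(lo, hi, 3))))
        for wi, t0 in enumerate(starts):
            j0 = int(round(t0 * rate))
            j1 = j0 + int(round(window * rate))
            feats[wi, bi] = env[j0:j1].mean()
    return starts, feats
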