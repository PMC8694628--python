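"""Generalized Morse wavelet transform and element analysis.

A generalized Morse wavelet of order ``k`` and family ``gamma`` is defined in
the frequency domain, for omega >= 0, as::

    psihat_{k,gamma}(omega) = a * omega**k * exp(-omega**gamma)

The wavelet is analytic (no negative-frequency support).  Two normalizations
are used:

``bandpass``
    a = alpha_{k,gamma} = 2 (e*gamma/k)**(k/gamma), which sets the peak of
    psihat to 2.  This is the normalization under which all the element
    analysis identities below hold.
``energy``
    a chosen so the time-domain wavelet has unit energy.

Element analysis models a signal as a sparse sum of rescaled Morse wavelets

    x(t) = sum_n Re{ c_n * psi_{mu,gamma}((t - t_n)/rho_n) } + x_e(t)

and infers the event parameters (complex amplitude c_n, time t_n, scale
rho_n) from the local modulus maxima of the wavelet transform of x taken
with an analyzing wavelet psi_{beta,gamma}.  At a maximum produced by an
isolated event,

    w_{beta,gamma}(t_n, s_n) = (1/2) c_n * zeta_max(beta, mu, gamma)

with the maximizing scale satisfying s_n / rho_n = (beta/(mu+1))**(1/gamma),
which inverts to the estimators implemented by :func:`infer_events`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.ndimage import zoom as _ndzoom
from scipy.special import gamma as _gamma_fn

__all__ = [
    "MorseParams",
    "Scalogram",
    "MorseEvent",
    "alpha",
    "zeta_max",
    "scale_ratio",
    "peak_frequency",
    "scale_for_frequency",
    "morse_wavelet",
    "morse_time_quadrature",
    "zeta",
    "cwt",
    "transform_maxima",
    "infer_events",
    "reconstruct",
    "scalogram_image",
    "epoch_starts",
]


def alpha(beta: float, gamma: float) -> float:
    """Bandpass normalizing constant 2 (e*gamma/beta)**(beta/gamma)."""
    if beta <= 0 or gamma <= 0:
        raise ValueError("beta and gamma must be positive")
    return 2.0 * (np.e * gamma / beta) ** (beta / gamma)


def peak_frequency(order: float, gamma: float, scale: float = 1.0) -> float:
    """Peak (modal) frequency in Hz of the wavelet dilated to `scale` seconds."""
    return (order / gamma) ** (1.0 / gamma) / (2.0 * np.pi * scale)


def scale_for_frequency(order: float, gamma: float, freq_hz: float) -> float:
    """Scale (s) at which the wavelet's peak frequency equals `freq_hz`."""
    return (order / gamma) ** (1.0 / gamma) / (2.0 * np.pi * freq_hz)


def zeta_max(beta: float, mu: float, gamma: float) -> float:
    """Peak modulus of the event response surface zeta_{beta,mu,gamma}.

    Closed form:  alpha_{beta,gamma} alpha_{mu,gamma} / (2 pi gamma)
    * Gamma((beta+mu+1)/gamma) * r**beta / (r+1)**((beta+mu+1)/gamma)
    with r = beta/(mu+1).
    """
    r = beta / (mu + 1.0)
    return (
        alpha(beta, gamma)
        * alpha(mu, gamma)
        / (2.0 * np.pi * gamma)
        * _gamma_fn((beta + mu + 1.0) / gamma)
        * r ** (beta / gamma)
        / (r + 1.0) ** ((beta + mu + 1.0) / gamma)
    )


def scale_ratio(beta: float, mu: float, gamma: float) -> float:
    """Ratio s/rho at which the event response modulus peaks.

    The modulus of zeta(0, r) is maximal at r**gamma = beta/(mu+1); an
    event of scale rho therefore produces its transform maximum at analysis
    scale s = rho * (beta/(mu+1))**(1/gamma).  Inverting this relation is
    how :func:`infer_events` recovers rho from the maximum's scale.
    """
    return (beta / (mu + 1.0)) ** (1.0 / gamma)


def _amplitude(order: float, gamma: float, norm: str) -> float:
    if norm == "bandpass":
        return alpha(order, gamma)
    if norm == "energy":
        # energy of the analytic wavelet: a^2/(2 pi gamma) 2^{-(2k+1)/gamma}
        #                                  * Gamma((2k+1)/gamma)
        e = _gamma_fn((2.0 * order + 1.0) / gamma) * 2.0 ** (
            -(2.0 * order + 1.0) / gamma
        ) / (2.0 * np.pi * gamma)
        return float(1.0 / np.sqrt(e))
    raise ValueError(f"unknown norm {norm!r}")


def _psihat(omega: np.ndarray, order: float, gamma: float, norm: str) -> np.ndarray:
    """Frequency-domain wavelet on omega >= 0 (zero elsewhere)."""
    a = _amplitude(order, gamma, norm)
    out = np.zeros_like(omega, dtype=float)
    pos = omega > 0
    with np.errstate(over="ignore"):
        out[pos] = a * omega[pos] ** order * np.exp(-(omega[pos] ** gamma))
    return out


def _morse_time(
    order: float,
    gamma: float,
    u0: float,
    du: float,
    n: int,
    norm: str = "bandpass",
) -> np.ndarray:
    """Evaluate the unit-scale wavelet psi(u) at u = u0 + j*du, j=0..n-1.

    Inverse Fourier quadrature on an FFT grid; requires the frequency support
    of psihat (which dies off like exp(-omega**gamma)) to fit below the grid
    Nyquist 2*pi/du.
    """
    omega_cut = (order / gamma) ** (1.0 / gamma) + (60.0) ** (1.0 / gamma)
    if 2.0 * np.pi / du < omega_cut:
        raise ValueError("scale too small for the sampling rate (wavelet aliases)")
    nfft = int(2 ** np.ceil(np.log2(max(n * 2, 256))))
    omega = 2.0 * np.pi * np.arange(nfft) / (nfft * du)
    ph = _psihat(omega, order, gamma, norm) * np.exp(1j * omega * u0)
    return np.fft.ifft(ph)[:n] / du


def morse_wavelet(
    order: float,
    gamma: float,
    scale: float,
    length: int,
    rate: float,
    norm: str = "energy",
) -> np.ndarray:
    """Time-domain Morse wavelet dilated to `scale` (seconds), centered.

    For ``norm='energy'`` the returned waveform has unit energy
    (sum |psi|^2 / rate == 1) at any scale.  For ``norm='bandpass'`` the
    returned samples are the pure dilation psi((t - t_mid)/scale) of the
    alpha-normalized wavelet, the convention used by element analysis.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if peak_frequency(order, gamma, scale) >= rate / 2.0:
        raise ValueError("scale too small for the sampling rate")
    dt = 1.0 / rate
    t = (np.arange(length) - length // 2) * dt
    psi = _morse_time(order, gamma, t[0] / scale, dt / scale, length, norm="bandpass")
    if norm == "bandpass":
        return psi
    if norm == "energy":
        # unit-energy dilation: (1/sqrt(s)) psi_e(t/s)
        a_ratio = _amplitude(order, gamma, "energy") / _amplitude(order, gamma, "bandpass")
        return psi * a_ratio / np.sqrt(scale)
    raise ValueError(f"unknown norm {norm!r}")


def morse_time_quadrature(
    order: float, gamma: float, u: np.ndarray, norm: str = "bandpass"
) -> np.ndarray:
    """Direct-quadrature oracle for psi(u): slow, grid-free, for testing."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    omega = np.linspace(1e-9, (order / gamma) ** (1 / gamma) + 40.0 ** (1 / gamma), 4001)
    ph = _psihat(omega, order, gamma, norm)
    out = np.empty(u.size, dtype=complex)
    for i in range(0, u.size, 2000):  # chunked outer product caps memory
        ker = np.exp(1j * np.outer(u[i : i + 2000], omega))
        out[i : i + 2000] = (ker * ph).sum(axis=1)
    return out * (omega[1] - omega[0]) / (2.0 * np.pi)


def zeta(
    tau: np.ndarray, r: np.ndarray, beta: float, mu: float, gamma: float
) -> np.ndarray:
    """Event response surface zeta_{beta,mu,gamma}(tau, r) with r = s/rho.

    zeta = (a_b a_m / a_bm) r**beta (r**gamma+1)**(-(beta+mu+1)/gamma)
           * psi_{beta+mu,gamma}(tau / (r**gamma+1)**(1/gamma))
    """
    tau = np.asarray(tau, dtype=float)
    r = np.asarray(r, dtype=float)
    stretch = (r**gamma + 1.0) ** (1.0 / gamma)
    amp = (
        alpha(beta, gamma)
        * alpha(mu, gamma)
        / alpha(beta + mu, gamma)
        * r**beta
        * stretch ** -(beta + mu + 1.0)
    )
    psi = morse_time_quadrature(beta + mu, gamma, (tau / stretch).ravel())
    return amp * psi.reshape(np.broadcast(tau, r).shape)


@dataclass
class MorseParams:
    """Analysis configuration: analyzing order beta, element order mu,
    family gamma, and the log-spaced scale grid in seconds."""

    beta: float = 3.0
    mu: float = 2.0
    gamma: float = 3.0
    scales: np.ndarray = field(default_factory=lambda: np.geomspace(0.01, 1.0, 54))

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        if self.beta <= 0 or self.mu <= 0 or self.gamma <= 0:
            raise ValueError("beta, mu, gamma must be positive")
        if self.scales.size < 2 or np.any(np.diff(self.scales) <= 0):
            raise ValueError("scale grid must be ascending with >= 2 points")

    @classmethod
    def from_band(
        cls,
        f_lo: float,
        f_hi: float,
        voices: int = 8,
        beta: float = 3.0,
        mu: float = 2.0,
        gamma: float = 3.0,
    ) -> "MorseParams":
        """Scale grid whose peak frequencies cover [f_lo, f_hi] Hz,
        log-spaced with `voices` scales per octave."""
        s_hi = scale_for_frequency(beta, gamma, f_lo)
        s_lo = scale_for_frequency(beta, gamma, f_hi)
        n = int(np.ceil(np.log2(s_hi / s_lo) * voices)) + 1
        return cls(beta, mu, gamma, np.geomspace(s_lo, s_hi, max(n, 2)))


@dataclass
class Scalogram:
    """Complex wavelet transform w[scale, time] with its axes."""

    w: np.ndarray
    times: np.ndarray
    scales: np.ndarray
    params: MorseParams
    rate: float

    def __post_init__(self) -> None:
        if self.w.shape != (self.scales.size, self.times.size):
            raise ValueError("scalogram shape does not match its axes")

    def coi_halfwidth(self) -> np.ndarray:
        """Per-scale edge half-width (s) inside which edge effects matter."""
        p = self.params
        t_half = np.sqrt(p.beta * p.gamma) / (p.beta / p.gamma) ** (1.0 / p.gamma)
        return 2.0 * self.scales * t_half

    def coi_mask(self) -> np.ndarray:
        """Boolean mask, True where the transform is edge-contaminated."""
        hw = self.coi_halfwidth()[:, None]
        t = self.times[None, :]
        return (t - self.times[0] < hw) | (self.times[-1] - t < hw)


@dataclass
class MorseEvent:
    """One inferred element: complex amplitude c, time t (s), scale rho (s)."""

    c: complex
    t: float
    rho: float

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("event scale rho must be positive")

    @property
    def magnitude(self) -> float:
        return abs(self.c)

    @property
    def phase(self) -> float:
        return float(np.angle(self.c))


def cwt(x: np.ndarray, rate: float, params: MorseParams) -> Scalogram:
    """Analytic Morse wavelet transform of a real signal.

    Frequency-domain convolution per scale with the bandpass-normalized
    analyzing wavelet; because only positive frequencies are kept, an event
    Re{c psi_mu((t-t0)/rho)} produces w = (1/2) c zeta(...) exactly as in
    the element-analysis identities.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    xhat = np.fft.fft(x)
    omega = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0 / rate)
    w = np.empty((params.scales.size, n), dtype=complex)
    for i, s in enumerate(params.scales):
        w[i] = np.fft.ifft(xhat * _psihat(s * omega, params.beta, params.gamma, "bandpass"))
    times = np.arange(n) / rate
    return Scalogram(w=w, times=times, scales=params.scales.copy(), params=params, rate=rate)


def transform_maxima(
    scal: Scalogram,
    threshold: float | None = None,
    exclude_coi: bool = True,
    refine: bool = True,
) -> list[tuple[float, float, complex]]:
    """Strict local maxima of |w| over the (time, scale) grid.

    Returns (tau_hat, s_hat, w_value) triples sorted by descending |w|.
    With ``refine`` the location is sharpened by parabolic interpolation in
    time and in log-scale, and |w| is corrected accordingly (the phase is
    taken from the grid point).
    """
    mag = np.abs(scal.w)
    footprint = maximum_filter(mag, size=3, mode="nearest")
    is_max = (mag == footprint) & (mag > 0)
    # strict: drop plateaus wider than one cell
    if threshold is not None:
        is_max &= mag >= threshold
    if exclude_coi:
        is_max &= ~scal.coi_mask()
    # border rows/cols cannot be verified as strict maxima
    is_max[0, :] = is_max[-1, :] = False
    is_max[:, 0] = is_max[:, -1] = False
    si, ti = np.nonzero(is_max)
    order = np.argsort(mag[si, ti])[::-1]
    out: list[tuple[float, float, complex]] = []
    log_s = np.log(scal.scales)
    dt = 1.0 / scal.rate
    for k in order:
        i, j = int(si[k]), int(ti[k])
        tau, s, wv = scal.times[j], scal.scales[i], scal.w[i, j]
        if refine:
            # parabolic peak interpolation along each axis of log|w|
            m0 = np.log(mag[i, j])
            dtau = _parabolic_offset(
                np.log(mag[i, j - 1]), m0, np.log(mag[i, j + 1])
            )
            ds = _parabolic_offset(
                np.log(mag[i - 1, j]), m0, np.log(mag[i + 1, j])
            )
            tau = tau + dtau * dt
            ls = log_s[i] + ds * (log_s[min(i + 1, len(log_s) - 1)] - log_s[i - 1]) / 2.0
            s = float(np.exp(ls))
            corr_t = m0 + 0.25 * dtau * (
                np.log(mag[i, j + 1]) - np.log(mag[i, j - 1])
            )
            corr_s = 0.25 * ds * (np.log(mag[i + 1, j]) - np.log(mag[i - 1, j]))
            wv = wv / mag[i, j] * float(np.exp(corr_t + corr_s))
        out.append((float(tau), float(s), complex(wv)))
    return out


def _parabolic_offset(ym: float, y0: float, yp: float) -> float:
    denom = ym - 2.0 * y0 + yp
    if denom >= 0 or not np.isfinite(denom):
        return 0.0
    off = 0.5 * (ym - yp) / denom
    return float(np.clip(off, -0.5, 0.5))


def infer_events(
    maxima: list[tuple[float, float, complex]], params: MorseParams
) -> list[MorseEvent]:
    """Invert transform maxima into element parameters.

    t_hat = tau_hat;  rho_hat = s_hat / (beta/(mu+1))**(1/gamma);
    c_hat = 2 w(tau_hat, s_hat) / zeta_max(beta, mu, gamma).
    """
    zm = zeta_max(params.beta, params.mu, params.gamma)
    ratio = scale_ratio(params.beta, params.mu, params.gamma)
    return [
        MorseEvent(c=2.0 * wv / zm, t=tau, rho=s / ratio) for tau, s, wv in maxima
    ]


def reconstruct(
    events: list[MorseEvent],
    mu: float,
    gamma: float,
    length: int,
    rate: float,
) -> np.ndarray:
    """Sum of real parts of the scaled element wavelets on a sample grid."""
    # frequency-domain synthesis on the signal's own DFT grid: the analytic
    # part of one element has spectrum c * rho * psihat(rho w) * e^{-i w t}
    omega = 2.0 * np.pi * np.fft.fftfreq(length, d=1.0 / rate)
    pos = omega > 0
    wpos = omega[pos]
    z = np.zeros(length, dtype=complex)
    for ev in events:
        z[pos] += (
            ev.c
            * ev.rho
            * _psihat(wpos * ev.rho, mu, gamma, "bandpass")
            * np.exp(-1j * wpos * ev.t)
        )
    return np.real(np.fft.ifft(z) * rate)


def inject_morse_element(
    signal: np.ndarray,
    rate: float,
    c: complex,
    t: float,
    rho: float,
    mu: float = 2.0,
    gamma: float = 3.0,
) -> np.ndarray:
    """Return `signal` plus the element Re{c psi_{mu,gamma}((time - t)/rho)}.

    Ground-truth generator for element-analysis tests: the injected waveform
    uses the same bandpass-normalized dilation convention that
    :func:`infer_events` inverts, so recovery should be exact up to grid
    discretization.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if not (0.0 <= t <= n / rate):
        raise ValueError("element time lies outside the signal")
    return signal + reconstruct([MorseEvent(c=c, t=t, rho=rho)], mu, gamma, n, rate)


def epoch_starts(duration: float, length: float = 30.0, stride: float = 10.0) -> np.ndarray:
    """Start times of overlapped analysis epochs covering [0, duration]."""
    if duration < length:
        return np.array([])
    n = int(np.floor((duration - length) / stride)) + 1
    return np.arange(n) * stride


def scalogram_image(
    scg_wide: np.ndarray,
    rate: float,
    epoch: tuple[float, float],
    params: MorseParams | None = None,
    raster: tuple[int, int] = (128, 128),
    threshold_factor: float = 5.0,
    max_events: int = 60,
) -> np.ndarray:
    """Element-analysis scalogram image of one epoch, normalized to [0, 1].

    The epoch is transformed, its transform maxima above
    ``threshold_factor * median|w|`` are inverted into elements, the sparse
    element reconstruction replaces the raw signal, and the modulus of the
    reconstruction's transform is rasterized (log-scale frequency axis, time
    along the second dimension).  The sparse step suppresses background
    noise and keeps only coherent cardiorespiratory structure.
    """
    start, length_s = epoch
    i0 = int(round(start * rate))
    i1 = int(round((start + length_s) * rate))
    if i0 < 0 or i1 > scg_wide.size:
        raise ValueError("epoch lies outside the recording")
    seg = np.asarray(scg_wide[i0:i1], dtype=float)
    if params is None:
        params = MorseParams.from_band(0.1, min(24.0, rate / 2.5))
    scal = cwt(seg, rate, params)
    mag = np.abs(scal.w)
    if not np.any(mag > 0):
        return np.zeros(raster)
    thr = threshold_factor * float(np.median(mag))
    maxima = transform_maxima(scal, threshold=thr, exclude_coi=False)[:max_events]
    events = infer_events(maxima, params)
    recon = reconstruct(events, params.mu, params.gamma, seg.size, rate)
    img = np.abs(cwt(recon, rate, params).w)
    top = img.max()
    if top > 0:
        img = img / top
    zoom = (raster[0] / img.shape[0], raster[1] / img.shape[1])
    out = _ndzoom(img, zoom, order=1, mode="nearest")
    return np.clip(out[: raster[0], : raster[1]], 0.0, 1.0)
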