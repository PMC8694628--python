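"""Generalized Morse wavelets and element analysis: closed forms against
numeric oracles, and injected-element round trips."""

import numpy as np
import pytest

from scoper import morse


RATE = 100.0
N = 6000


@pytest.fixture(scope="module")
def band_params():
    return morse.MorseParams.from_band(0.1, 10.0, voices=8)


def test_alpha_closed_form():
    # beta = gamma gives 2e exactly
    assert morse.alpha(3, 3) == pytest.approx(2 * np.e, rel=1e-12)
    for g in (1.0, 2.0, 3.5):
        assert morse.alpha(g, g) == pytest.approx(2 * np.e, rel=1e-12)
    # direct evaluation
    assert morse.alpha(2, 3) == pytest.approx(2 * (np.e * 3 / 2) ** (2 / 3), rel=1e-12)


def test_alpha_monotone_beyond_e_gamma():
    gammas = [1.0, 2.0, 4.0]
    for g in gammas:
        betas = np.linspace(np.e * g + 0.5, np.e * g + 10, 30)
        vals = [morse.alpha(b, g) for b in betas]
        assert np.all(np.diff(vals) < 0)


@pytest.mark.parametrize("order,gamma,scale", [(3, 3, 0.05), (2, 3, 0.1), (4, 2, 0.2)])
def test_wavelet_unit_energy_and_peak_frequency(order, gamma, scale):
    psi = morse.morse_wavelet(order, gamma, scale, 8192, 500.0, norm="energy")
    assert np.sum(np.abs(psi) ** 2) / 500.0 == pytest.approx(1.0, abs=1e-6)
    spec = np.abs(np.fft.fft(psi))
    f = np.fft.fftfreq(psi.size, 1 / 500.0)
    f_peak = abs(f[np.argmax(spec)])
    expect = morse.peak_frequency(order, gamma, scale)
    # agreement within 1 % or one FFT bin, whichever is larger
    assert abs(f_peak - expect) <= max(0.01 * expect, 500.0 / psi.size)


def test_doubling_scale_halves_peak_frequency():
    assert morse.peak_frequency(3, 3, 0.2) == pytest.approx(
        morse.peak_frequency(3, 3, 0.1) / 2
    )


def test_scale_guard():
    with pytest.raises(ValueError):
        morse.morse_wavelet(3, 3, 1e-5, 1024, 100.0)
    with pytest.raises(ValueError):
        morse.morse_wavelet(3, 3, -1.0, 1024, 100.0)


@pytest.mark.parametrize("beta,mu,gamma", [(2, 2, 3), (3, 2, 3), (3, 3, 2)])
def test_zeta_max_matches_numeric_maximization(beta, mu, gamma):
    closed = morse.zeta_max(beta, mu, gamma)
    rs = np.geomspace(0.3, 4.0, 151)
    brute = max(
        float(np.abs(morse.zeta(np.linspace(-2, 2, 121), r, beta, mu, gamma)).max())
        for r in rs
    )
    assert closed == pytest.approx(brute, rel=5e-3)


def test_zeta_max_pinned_regression_value():
    # frozen from the first verified run of the brute-force oracle
    assert morse.zeta_max(2, 2, 3) == pytest.approx(0.40647109435, rel=1e-8)


def test_zeta_max_finite_positive_on_grid():
    for b in (1, 4, 10):
        for m in (1, 5, 10):
            for g in (1, 2, 4):
                v = morse.zeta_max(b, m, g)
                assert np.isfinite(v) and v > 0


def test_cwt_zero_and_linearity(band_params):
    rng = np.random.default_rng(0)
    z = morse.cwt(np.zeros(2000), RATE, band_params)
    assert np.all(z.w == 0)
    x = rng.standard_normal(2000)
    y = rng.standard_normal(2000)
    wxy = morse.cwt(2 * x + 3 * y, RATE, band_params).w
    wx = morse.cwt(x, RATE, band_params).w
    wy = morse.cwt(y, RATE, band_params).w
    assert np.allclose(wxy, 2 * wx + 3 * wy, atol=1e-10)


def test_cwt_sinusoid_ridge(band_params):
    f0 = 2.0
    t = np.arange(N) / RATE
    scal = morse.cwt(np.sin(2 * np.pi * f0 * t), RATE, band_params)
    mid = N // 2
    ridge = scal.scales[np.argmax(np.abs(scal.w[:, mid]))]
    expect = morse.scale_for_frequency(band_params.beta, band_params.gamma, f0)
    step = scal.scales[1] / scal.scales[0]
    assert abs(np.log(ridge / expect)) <= np.log(step)


def test_single_element_maximum_count(band_params):
    x = morse.inject_morse_element(np.zeros(N), RATE, 1.0, 30.0, 0.4)
    scal = morse.cwt(x, RATE, band_params)
    maxima = morse.transform_maxima(scal, threshold=0.1)
    assert len(maxima) == 1


def test_two_separated_elements_two_maxima(band_params):
    # well-separated equal elements give exactly two primary maxima; the
    # threshold is set just under the theoretical single-element peak
    # (zeta_max/2) to exclude the weaker interference maxima at larger
    # scales, which are genuine features of the modulus surface
    rho = 0.4
    x = np.zeros(N)
    x = morse.inject_morse_element(x, RATE, 1.0, 25.0, rho)
    x = morse.inject_morse_element(x, RATE, 1.0, 25.0 + 10 * rho, rho)
    scal = morse.cwt(x, RATE, band_params)
    thr = 0.9 * morse.zeta_max(band_params.beta, band_params.mu, band_params.gamma) / 2
    maxima = morse.transform_maxima(scal, threshold=thr)
    assert len(maxima) == 2
    # interference with the neighbor pulls each peak slightly outward
    times = sorted(m[0] for m in maxima)
    assert times[0] == pytest.approx(25.0, abs=0.3)
    assert times[1] == pytest.approx(29.0, abs=0.3)


def test_noise_maxima_below_element_scale(band_params):
    rng = np.random.default_rng(5)
    x = rng.normal(0, 0.01, N)
    scal = morse.cwt(x, RATE, band_params)
    thr = 5.0 * float(np.median(np.abs(scal.w)))
    maxima = morse.transform_maxima(scal, threshold=thr)
    # an element of |c| = 1 produces |w| = zeta_max/2 ~ 0.18; noise stays far below
    for _, _, wv in maxima:
        assert abs(wv) < 0.05


def test_event_recovery_zero_noise(band_params):
    c_true = 1.0 * np.exp(1j * np.pi / 2)
    x = morse.inject_morse_element(np.zeros(N), RATE, c_true, 30.0, 0.5)
    scal = morse.cwt(x, RATE, band_params)
    ev = morse.infer_events(morse.transform_maxima(scal, threshold=0.05)[:1], band_params)[0]
    assert abs(ev.t - 30.0) <= 1.0 / RATE
    assert abs(abs(ev.c) - 1.0) <= 0.02
    assert ev.phase == pytest.approx(np.pi / 2, abs=0.05)
    log_step = np.log(band_params.scales[1] / band_params.scales[0])
    assert abs(np.log(ev.rho / 0.5)) <= log_step


def test_amplitude_linearity(band_params):
    def infer_mag(a):
        x = morse.inject_morse_element(np.zeros(N), RATE, a, 30.0, 0.5)
        scal = morse.cwt(x, RATE, band_params)
        return abs(
            morse.infer_events(
                morse.transform_maxima(scal, threshold=0.01)[:1], band_params
            )[0].c
        )

    assert infer_mag(2.0) == pytest.approx(2 * infer_mag(1.0), rel=1e-6)


def test_parameter_recovery_grid_under_noise():
    """Median |c| relative error <= 2 % / 10 % / 25 % at SNR inf / 10 / 3."""
    rng = np.random.default_rng(7)
    combos = [
        (abs_c, t0, rho)
        for abs_c in (0.5, 1.0)
        for t0 in (20.0, 30.0, 40.0)
        for rho in (0.25, 0.5)
    ]
    for mu, gamma in ((2.0, 3.0), (3.0, 3.0)):
        params = morse.MorseParams.from_band(0.1, 10.0, voices=8, mu=mu, gamma=gamma)
        for snr, tol in ((np.inf, 0.02), (10.0, 0.10), (3.0, 0.25)):
            errs = []
            for abs_c, t0, rho in combos:
                x = morse.inject_morse_element(
                    np.zeros(N), RATE, abs_c, t0, rho, mu=mu, gamma=gamma
                )
                if np.isfinite(snr):
                    sig_rms = np.sqrt(np.mean(x**2))
                    x = x + rng.normal(0, sig_rms / np.sqrt(snr), N)
                scal = morse.cwt(x, RATE, params)
                maxima = morse.transform_maxima(scal, threshold=0.02)
                if not maxima:
                    errs.append(1.0)
                    continue
                best = min(maxima, key=lambda m: abs(m[0] - t0))
                ev = morse.infer_events([best], params)[0]
                errs.append(abs(abs(ev.c) - abs_c) / abs_c)
            assert np.median(errs) <= tol


def test_reconstruct_empty_and_linearity():
    assert np.all(morse.reconstruct([], 2, 3, 500, RATE) == 0)
    e1 = morse.MorseEvent(c=1.0, t=2.0, rho=0.3)
    e2 = morse.MorseEvent(c=0.5j, t=3.0, rho=0.2)
    both = morse.reconstruct([e1, e2], 2, 3, 500, RATE)
    sep = morse.reconstruct([e1], 2, 3, 500, RATE) + morse.reconstruct([e2], 2, 3, 500, RATE)
    assert np.allclose(both, sep, atol=1e-12)


def test_three_element_round_trip(band_params):
    x = np.zeros(N)
    for c, t0, rho in [(1.0, 15.0, 0.3), (0.8j, 30.0, 0.6), (-0.5, 45.0, 0.15)]:
        x = morse.inject_morse_element(x, RATE, c, t0, rho)
    scal = morse.cwt(x, RATE, band_params)
    evs = morse.infer_events(morse.transform_maxima(scal, threshold=0.05)[:3], band_params)
    recon = morse.reconstruct(evs, band_params.mu, band_params.gamma, N, RATE)
    assert np.sum((x - recon) ** 2) <= 0.05 * np.sum(x**2)


def test_inject_identities():
    x = np.random.default_rng(1).standard_normal(1000)
    assert np.allclose(morse.inject_morse_element(x, RATE, 0.0, 5.0, 0.3), x)
    y = morse.inject_morse_element(x, RATE, 1.0, 5.0, 0.3)
    y = morse.inject_morse_element(y, RATE, -1.0, 5.0, 0.3)
    assert np.allclose(y, x, atol=1e-12)
    with pytest.raises(ValueError):
        morse.inject_morse_element(x, RATE, 1.0, 5.0, -0.1)


def test_injected_energy_matches_quadrature_oracle():
    c, rho = 0.7 + 0.2j, 0.4
    x = morse.inject_morse_element(np.zeros(N), RATE, c, 30.0, rho)
    energy = np.sum(x**2) / RATE
    # oracle: rho * integral of Re{c psi(u)}^2 du by direct quadrature
    u = np.linspace(-25, 25, 8001)
    psi = morse.morse_time_quadrature(2, 3, u)
    oracle = rho * np.trapezoid(np.real(c * psi) ** 2, u)
    assert energy == pytest.approx(oracle, rel=1e-3)


def test_epoch_starts_count():
    assert morse.epoch_starts(300.0).size == 28  # floor((300-30)/10)+1
    assert morse.epoch_starts(29.0).size == 0


def test_scalogram_image_zero_signal():
    img = morse.scalogram_image(np.zeros(64 * 40), 64.0, (0.0, 30.0), raster=(32, 32))
    assert img.shape == (32, 32)
    assert np.all(img == 0)


def test_scalogram_image_epoch_bounds():
    with pytest.raises(ValueError):
        morse.scalogram_image(np.zeros(64 * 40), 64.0, (20.0, 30.0))
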