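"""R-peak detection, HR/HRV, SCG ensembles, fiducials, kinetic energy."""

import numpy as np
import pytest

from scoper import cardiac, synth
from scoper.preprocess import ECG_BAND, SCG_BAND, bandpass


def _make(duration=60.0, hr=60, hrv_sd=0.0, pep=80, lvet=300, noise=None, seed=0):
    st = synth.PhysioState(hr=hr, hrv_sd=hrv_sd, rr=14, pep=pep, lvet=lvet,
                           ao_mag=0.04, motion_amp=0.0)
    script = synth.EventScript(duration=duration, stage_plan=[(0.0, "light")])
    rec, _, truth = synth.generate_recording(
        states={"light": st}, script=script, noise_sd=noise, seed=seed,
        return_truth=True,
    )
    return rec, truth


def test_r_peaks_clean_60bpm():
    rec, truth = _make()
    ecg = bandpass(rec["ecg"].samples, 128, ECG_BAND)
    beats = cardiac.detect_r_peaks(ecg, 128)
    assert abs(len(beats) - 60) <= 1
    for tb in truth.beat_times[1:-1]:
        assert np.min(np.abs(beats.r_times - tb)) <= 0.010


def test_r_peaks_flatline_flagged():
    beats = cardiac.detect_r_peaks(np.zeros(128 * 30), 128)
    assert len(beats) == 0
    assert beats.low_quality


def test_r_peaks_under_noise():
    # noise sd = 0.2 x R amplitude (R ~ 1 mV)
    rec, truth = _make(noise={"ecg": 0.2}, seed=4)
    ecg = bandpass(rec["ecg"].samples, 128, ECG_BAND)
    beats = cardiac.detect_r_peaks(ecg, 128)
    hits = [np.min(np.abs(beats.r_times - tb)) <= 0.020 for tb in truth.beat_times[1:-1]]
    assert np.mean(hits) >= 0.98


def test_hr_hrv_closed_forms():
    b = cardiac.BeatTable(np.arange(30) * 1.0 + 0.5, np.ones(30))
    df = cardiac.hr_hrv_series(b, window=30.0, step=30.0)
    assert df.hr.iloc[0] == pytest.approx(60.0)
    assert df.sdnn.iloc[0] == pytest.approx(0.0, abs=1e-9)
    assert df.rmssd.iloc[0] == pytest.approx(0.0, abs=1e-9)
    fast = cardiac.BeatTable(np.arange(60) * 0.5 + 0.25, np.ones(60))
    assert cardiac.hr_hrv_series(fast, 30, 30).hr.iloc[0] == pytest.approx(120.0)
    # alternating 0.9/1.1 s RR: every successive difference is 0.2 s
    times = np.concatenate([[0.0], np.cumsum(np.tile([0.9, 1.1], 15))])
    alt = cardiac.BeatTable(times, np.ones(times.size))
    assert cardiac.hr_hrv_series(alt, 31, 31).rmssd.iloc[0] == pytest.approx(200.0, rel=1e-6)


def test_hr_missing_window_markers():
    b = cardiac.BeatTable(np.array([0.5, 1.5, 2.5, 100.0, 101.0, 102.0]), np.ones(6))
    df = cardiac.hr_hrv_series(b, window=30.0, step=30.0)
    assert np.isnan(df.hr.iloc[1])  # empty middle window


def test_ensemble_identical_beats_and_exclusion():
    rate = 500.0
    beat = np.sin(np.linspace(0, 4 * np.pi, 250))
    sig = np.tile(beat, 12)
    times = np.arange(10) * 0.5 + 0.0
    q = np.ones(10)
    q[3] = 0.1  # excluded
    ens = cardiac.segment_and_ensemble(sig, rate, cardiac.BeatTable(times + 1.0, q), 0.5)
    assert ens.beat_count == 9
    assert np.allclose(ens.average, ens.matrix[0])


def test_ensemble_noise_reduction_clt():
    rng = np.random.default_rng(0)
    rate, n_beats, sigma = 500.0, 200, 0.3
    beat = np.sin(np.linspace(0, 4 * np.pi, 250))
    sig = np.tile(beat, n_beats + 2) + rng.normal(0, sigma, 250 * (n_beats + 2))
    times = np.arange(n_beats) * 0.5 + 0.5
    ens = cardiac.segment_and_ensemble(
        sig, rate, cardiac.BeatTable(times, np.ones(n_beats)), 0.5
    )
    resid = ens.average - beat
    assert resid.std() <= 1.2 * sigma / np.sqrt(n_beats)


def test_ensemble_requires_beats():
    with pytest.raises(ValueError):
        cardiac.segment_and_ensemble(
            np.zeros(100), 500.0, cardiac.BeatTable(np.array([]), np.array([])), 0.1
        )


def test_fiducials_recover_configured_timing():
    rec, truth = _make(pep=80, lvet=300)
    ecg = bandpass(rec["ecg"].samples, 128, ECG_BAND)
    scg = bandpass(rec["acc_z"].samples, 500, SCG_BAND)
    beats = cardiac.detect_r_peaks(ecg, 128)
    ens = cardiac.segment_and_ensemble(scg, 500, beats, 0.5)
    fid = cardiac.detect_fiducials(ens)
    assert fid.ao == pytest.approx(0.080, abs=0.005)
    assert fid.pep == pytest.approx(fid.ao * 1000.0)  # definitional
    assert fid.lvet == pytest.approx(300.0, abs=10.0)
    assert fid.ao < fid.acm < fid.ac  # ordering invariant


@pytest.mark.parametrize("pep,lvet", [(60, 250), (90, 300), (120, 350)])
def test_pep_lvet_sweep_recovery(pep, lvet):
    rec, _ = _make(pep=pep, lvet=lvet)
    ecg = bandpass(rec["ecg"].samples, 128, ECG_BAND)
    scg = bandpass(rec["acc_z"].samples, 500, SCG_BAND)
    beats = cardiac.detect_r_peaks(ecg, 128)
    ens = cardiac.segment_and_ensemble(scg, 500, beats, 0.55)
    fid = cardiac.detect_fiducials(ens, ao_window=(0.02, 0.16), ac_window=(0.25, 0.50))
    assert abs(fid.pep - pep) <= 10.0
    assert abs(fid.lvet - lvet) <= 10.0


def test_fiducial_empty_window_flagged():
    rate = 500.0
    avg = np.zeros(100)  # 0.2-s beat: the S2 window is off the end
    ens = cardiac.ScgEnsemble(np.tile(avg, (3, 1)), rate, 0.2, np.arange(3.0))
    fid = cardiac.detect_fiducials(ens)
    assert fid.ac is None
    assert "ac_missing" in fid.flags


def test_time_shift_equivariance():
    rec, _ = _make(duration=40.0)
    shift_s = 2.0
    ecg = bandpass(rec["ecg"].samples, 128, ECG_BAND)
    b1 = cardiac.detect_r_peaks(ecg, 128)
    b2 = cardiac.detect_r_peaks(ecg[int(shift_s * 128) :], 128)
    common = min(len(b1.r_times[b1.r_times > shift_s + 0.5]), len(b2))
    shifted = b1.r_times[b1.r_times > shift_s + 0.5][:common] - shift_s
    kept = b2.r_times[b2.r_times > 0.5][:common]
    assert np.all(np.abs(shifted - kept) <= 1.5 / 128)


def test_kinetic_energy_bands():
    rate = 500.0
    t = np.arange(int(60 * rate)) / rate
    starts, feats = cardiac.kinetic_energy_bands(np.zeros(t.size), rate)
    assert feats.shape == (23, 4)  # floor((60-5)/2.5)+1
    assert np.allclose(feats, 0)
    a = 0.7
    starts, feats = cardiac.kinetic_energy_bands(a * np.sin(2 * np.pi * 22.0 * t), rate)
    mid = slice(2, -2)
    assert np.median(feats[mid, 0]) == pytest.approx(a, rel=0.05)  # 20-25 Hz band
    assert np.max(feats[mid, 3]) <= 0.05 * a  # 35-40 Hz band
    with pytest.raises(ValueError):
        cardiac.kinetic_energy_bands(np.zeros(100), 60.0)
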