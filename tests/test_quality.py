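"""Periodicity, DTW repeatability, and the quality gate."""

import numpy as np
import pandas as pd
import pytest

from scoper import quality
from scoper.cardiac import BeatTable


def periodic_fixture(n_beats=40, rate=128.0, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    period = 1.0
    beat = np.exp(-0.5 * ((np.arange(int(rate)) / rate - 0.3) / 0.02) ** 2)
    x = np.tile(beat, n_beats)
    times = np.arange(n_beats) * period + 0.3
    if jitter:
        times = times + rng.normal(0, jitter, n_beats)
    return x, BeatTable(np.sort(times), np.ones(n_beats)), rate


def test_periodicity_of_periodic_signal_is_one():
    x, beats, rate = periodic_fixture()
    p = quality.periodicity(x, rate, beats)
    assert p["one_beat"] == pytest.approx(1.0, abs=0.01)
    assert p["two_beat"] == pytest.approx(1.0, abs=0.01)


def test_periodicity_of_noise_is_near_zero():
    _, beats, rate = periodic_fixture()
    rng = np.random.default_rng(3)
    x = rng.standard_normal(int(40 * rate))
    assert quality.periodicity(x, rate, beats)["one_beat"] <= 0.1


def test_periodicity_equal_power_mixture():
    # periodic + equal-power noise: the lagged peak carries the signal
    # power fraction, 0.5
    x, beats, rate = periodic_fixture()
    rng = np.random.default_rng(4)
    noise = rng.standard_normal(x.size)
    noise *= np.sqrt(np.mean(x**2) / np.mean(noise**2))
    mix = x + noise
    p = quality.periodicity(mix, rate, beats)["one_beat"]
    assert p == pytest.approx(0.5, abs=0.1)


def test_periodicity_needs_beats():
    with pytest.raises(ValueError):
        quality.periodicity(np.zeros(100), 10.0, BeatTable(np.array([0.0]), np.array([1.0])))


def test_dtw_identical_beats_score_zero():
    beat = np.sin(np.linspace(0, 6 * np.pi, 200))
    m = np.tile(beat, (10, 1))
    assert quality.dtw_repeatability(m) == pytest.approx(0.0, abs=1e-9)


def test_dtw_absorbs_local_tempo_warps():
    # +-10 % local tempo copies of one template: DTW aligns them almost
    # perfectly, while the unwarped RMS distance stays large
    t = np.linspace(0, 1, 2500)
    template = np.sin(2 * np.pi * 3 * t) + 0.5 * np.sin(2 * np.pi * 7 * t)
    rows = []
    for a in (-1.0, -0.5, 0.0, 0.5, 1.0):
        # smooth monotone warp with local tempo within +-10 %
        warped_t = t + a * 0.008 * np.sin(2 * np.pi * t)
        rows.append(np.interp(np.clip(warped_t, 0, 1), t, template))
    m = np.vstack(rows)
    avg = m.mean(axis=0)
    unwarped_rms = np.mean([np.sqrt(np.mean((r - avg) ** 2)) for r in m])
    assert quality.dtw_repeatability(m, z_normalize=False) <= 0.10 * unwarped_rms


def test_dtw_monotone_in_noise():
    rng = np.random.default_rng(5)
    beat = np.sin(np.linspace(0, 6 * np.pi, 200))
    scores = []
    for s in (0.0, 0.05, 0.1, 0.2):
        m = np.tile(beat, (10, 1)) + rng.normal(0, s, (10, 200))
        scores.append(quality.dtw_repeatability(m))
    assert np.all(np.diff(scores) >= -1e-12)


def test_dtw_amplitude_scaling_behaviour():
    rng = np.random.default_rng(6)
    m = np.tile(np.sin(np.linspace(0, 6 * np.pi, 150)), (6, 1))
    m += rng.normal(0, 0.1, m.shape)
    base_z = quality.dtw_repeatability(10 * m, z_normalize=True)
    assert base_z == pytest.approx(quality.dtw_repeatability(m, z_normalize=True), rel=1e-9)
    base_raw = quality.dtw_repeatability(m, z_normalize=False)
    assert quality.dtw_repeatability(10 * m, z_normalize=False) == pytest.approx(
        10 * base_raw, rel=1e-6
    )


def _metrics(per, rep):
    return pd.DataFrame({"periodicity": per, "repeatability": rep})


def test_gate_extreme_thresholds():
    m = _metrics([0.3, 0.8, 0.5], [0.1, 0.2, 0.3])
    all_pass, frac = quality.quality_gate(
        m, quality.QualityThresholds(min_periodicity=0.0, max_repeatability=np.inf)
    )
    assert all_pass.all() and frac == 0.0
    none_pass, frac = quality.quality_gate(
        m, quality.QualityThresholds(min_periodicity=1.1, max_repeatability=-1.0)
    )
    assert not none_pass.any() and frac == 1.0


def test_gate_rejects_noise_segments():
    # 10 % of segments swapped for noise-like metrics
    per = np.full(50, 0.6)
    rep = np.full(50, 0.1)
    bad = [4, 14, 24, 34, 44]
    per[bad] = 0.02
    rep[bad] = 0.8
    accept, frac = quality.quality_gate(_metrics(per, rep))
    assert frac == pytest.approx(0.10, abs=1e-9)
    assert not accept[bad].any()
    assert accept[[i for i in range(50) if i not in bad]].all()


def test_gate_monotone_in_thresholds():
    rng = np.random.default_rng(7)
    m = _metrics(rng.uniform(0, 1, 100), rng.uniform(0, 1, 100))
    strict, _ = quality.quality_gate(
        m, quality.QualityThresholds(min_periodicity=0.5, max_repeatability=0.4)
    )
    relaxed, _ = quality.quality_gate(
        m, quality.QualityThresholds(min_periodicity=0.3, max_repeatability=0.6)
    )
    # relaxing both thresholds never rejects a previously accepted segment
    assert np.all(relaxed >= strict)
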