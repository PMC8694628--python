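"""Synthetic multimodal cardiorespiratory generator.

Produces a :class:`~scoper.io.Recording` (ECG 128 Hz, 3-axis acceleration
500 Hz, red/IR PPG 50 Hz) with a ground-truth :class:`~scoper.io.AnnotationTrack`
so every downstream estimator can be validated without real data.

The model is phenomenological, not mechanistic:

* ECG is a repeated sum-of-Gaussians PQRST template; beat times follow the
  stage heart rate with Gaussian inter-beat jitter (the HRV knob).
* The seismocardiogram rides on the dorso-ventral accelerometer axis as
  Gaussian-windowed tone bursts: an AO complex `pep` ms after each R peak,
  an AC complex `pep + lvet` ms after R, and a smaller ACM burst 40 ms
  before AC.
* Respiration is a tidal sinusoid on the dorso-ventral axis; gravity is a
  unit vector set by body position; wake adds band-limited movement.
* The two PPG channels share one cardiac pulse waveform whose red/IR
  amplitude ratio encodes SpO2 through the inverse of the pulse-oximetry
  calibration line.
* During a scripted apnea/hypopnea the tidal amplitude is scaled by
  (1 - severity); SpO2 relaxes toward a desaturated level after a 10-s
  central-to-peripheral transport delay (fall tau 20 s, recovery tau 10 s);
  for 15 s after the event ends a sympathetic transient raises HR and
  lowers PEP, LVET and |AO| in proportion to severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import AnnotationTrack, Channel, Recording
from .morse import inject_morse_element  # re-exported: ground truth for morse tests

__all__ = [
    "PhysioState",
    "EventScript",
    "GroundTruth",
    "STAGE_STATES",
    "generate_recording",
    "inject_morse_element",
]

RATES = {"ecg": 128.0, "acc": 500.0, "ppg": 50.0}
_GRAVITY = {
    "supine": np.array([0.0, 0.0, -1.0]),
    "left": np.array([0.0, 1.0, 0.0]),
    "prone": np.array([0.0, 0.0, 1.0]),
    "right": np.array([0.0, -1.0, 0.0]),
}


@dataclass(frozen=True)
class PhysioState:
    """Quasi-stationary physiological operating point."""

    hr: float = 60.0          # bpm
    hrv_sd: float = 30.0      # ms, inter-beat jitter
    rr: float = 14.0          # breaths/min
    re_amp: float = 0.02      # g, tidal acceleration amplitude
    spo2: float = 97.0        # %
    pep: float = 90.0         # ms, R -> AO
    lvet: float = 300.0       # ms, AO -> AC
    ao_mag: float = 0.04      # g, AO burst amplitude
    position: str = "supine"
    motion_amp: float = 0.0   # g, 0.7-3 Hz movement (actigraphy driver)

    def validate(self) -> None:
        if not (20 <= self.hr <= 220):
            raise ValueError(f"hr {self.hr} outside [20, 220] bpm")
        if not (4 <= self.rr <= 40):
            raise ValueError(f"rr {self.rr} outside [4, 40] breaths/min")
        if not (0 <= self.spo2 <= 100):
            raise ValueError("spo2 outside [0, 100]")
        if self.pep + self.lvet >= 60000.0 / self.hr:
            raise ValueError("pep + lvet does not fit within one beat")
        if self.position not in _GRAVITY:
            raise ValueError(f"unknown position {self.position!r}")


#: Stage-dependent defaults: recoverable by design, not claimed physiology.
STAGE_STATES: dict[str, PhysioState] = {
    "wake": PhysioState(hr=70, hrv_sd=30, rr=15, re_amp=0.020, pep=95, lvet=300,
                        ao_mag=0.040, motion_amp=0.030),
    "light": PhysioState(hr=60, hrv_sd=40, rr=13, re_amp=0.025, pep=100, lvet=310,
                         ao_mag=0.035, motion_amp=0.003),
    "deep": PhysioState(hr=55, hrv_sd=25, rr=12, re_amp=0.030, pep=105, lvet=320,
                        ao_mag=0.030, motion_amp=0.002),
    "rem": PhysioState(hr=66, hrv_sd=60, rr=16, re_amp=0.018, pep=78, lvet=290,
                       ao_mag=0.045, motion_amp=0.001),
}


@dataclass
class EventScript:
    """Scripted breathing events and the sleep-stage plan."""

    duration: float
    events: list[tuple[float, float, str, float]] = field(default_factory=list)
    #: (onset s, duration s, type in {apnea, hypopnea}, severity in [0, 1])
    stage_plan: list[tuple[float, str]] = field(default_factory=lambda: [(0.0, "wake")])

    def __post_init__(self) -> None:
        # raw events may overlap (a simultaneous apnea + hypopnea); the
        # 10-s merge rule collapses them into one scored event
        self.events = sorted(self.events, key=lambda e: e[0])
        for onset, dur, typ, sev in self.events:
            if dur < 10.0:
                raise ValueError("scored events must last >= 10 s")
            if not (0.0 <= sev <= 1.0):
                raise ValueError("severity must lie in [0, 1]")
            if onset + dur > self.duration:
                raise ValueError("event extends beyond the recording")

    def stage_at(self, t: float) -> str:
        label = self.stage_plan[0][1]
        for start, s in self.stage_plan:
            if start <= t:
                label = s
        return label

    def merged_events(self, min_gap: float = 10.0) -> list[tuple[float, float, str]]:
        """Scored events after the rule that no two events may occur within
        `min_gap` seconds: closer events are merged into one."""
        merged: list[list] = []
        for onset, dur, typ, sev in self.events:
            if merged and onset - merged[-1][1] < min_gap:
                merged[-1][1] = max(merged[-1][1], onset + dur)
                if typ == "apnea":
                    merged[-1][2] = "apnea"
            else:
                merged.append([onset, onset + dur, typ])
        return [tuple(m) for m in merged]


@dataclass
class GroundTruth:
    """Per-control-sample truth series (10 Hz grid) plus beat times."""

    t: np.ndarray
    hr: np.ndarray
    rr: np.ndarray
    re_amp: np.ndarray
    spo2: np.ndarray
    pep: np.ndarray
    lvet: np.ndarray
    ao_mag: np.ndarray
    stage: list[str]
    position: list[str]
    beat_times: np.ndarray


def _control_series(
    states: dict[str, PhysioState],
    script: EventScript,
    max_desat_pct: float,
    ctrl_rate: float = 10.0,
) -> GroundTruth:
    n = int(round(script.duration * ctrl_rate))
    t = np.arange(n) / ctrl_rate
    stage = [script.stage_at(ti) for ti in t]
    base = {f: np.array([getattr(states[s], f) for s in stage], dtype=float) for f in
            ("hr", "rr", "re_amp", "spo2", "pep", "lvet", "ao_mag", "motion_amp")}
    position = [states[s].position for s in stage]
    hr, pep, lvet, ao = (base[k].copy() for k in ("hr", "pep", "lvet", "ao_mag"))
    re_amp = base["re_amp"].copy()
    # event effects
    desat_target = base["spo2"].copy()
    for onset, dur, typ, sev in script.events:
        offset = onset + dur
        inside = (t >= onset) & (t < offset)
        re_amp[inside] *= 1.0 - sev
        delayed = (t >= onset + 10.0) & (t < offset + 10.0)
        desat_target[delayed] -= max_desat_pct * sev
        post = (t >= offset) & (t < offset + 15.0)
        hr[post] += 12.0 * sev
        pep[post] -= 12.0 * sev
        lvet[post] -= 20.0 * sev
        ao[post] *= 1.0 + 0.5 * sev
    # first-order SpO2 kinetics: fall tau 20 s, recovery tau 10 s
    spo2 = np.empty(n)
    spo2[0] = desat_target[0]
    dt = 1.0 / ctrl_rate
    for i in range(1, n):
        tau = 20.0 if desat_target[i] < spo2[i - 1] else 10.0
        spo2[i] = spo2[i - 1] + (desat_target[i] - spo2[i - 1]) * (dt / tau)
    return GroundTruth(
        t=t, hr=hr, rr=base["rr"], re_amp=re_amp, spo2=np.clip(spo2, 0, 100),
        pep=pep, lvet=lvet, ao_mag=ao, stage=stage, position=position,
        beat_times=np.array([]),
    ), base["motion_amp"]


def _ecg_template(dt_rel: np.ndarray) -> np.ndarray:
    """Sum-of-Gaussians PQRST morphology (mV), R centred at 0."""
    lobes = [  # (offset s, width s, amplitude mV)
        (-0.20, 0.025, 0.12),   # P
        (-0.028, 0.010, -0.12), # Q
        (0.0, 0.009, 1.00),     # R
        (0.030, 0.011, -0.22),  # S
        (0.22, 0.045, 0.30),    # T
    ]
    out = np.zeros_like(dt_rel)
    for off, w, a in lobes:
        out += a * np.exp(-0.5 * ((dt_rel - off) / w) ** 2)
    return out


def _burst(dt_rel: np.ndarray, center: float, amp: float,
           carrier_hz: float = 22.0, sigma: float = 0.012) -> np.ndarray:
    """Gaussian-windowed tone: symmetric, largest positive peak at `center`."""
    u = dt_rel - center
    return amp * np.cos(2 * np.pi * carrier_hz * u) * np.exp(-0.5 * (u / sigma) ** 2)


def generate_recording(
    states: dict[str, PhysioState] | None = None,
    script: EventScript | None = None,
    noise_sd: dict[str, float] | None = None,
    seed: int = 0,
    max_desat_pct: float = 35.0,
    dc_levels: tuple[float, float] = (20000.0, 30000.0),
    perfusion_ir: float = 0.02,
    spo2_calib: tuple[float, float] = (110.0, 25.0),
    return_truth: bool = False,
):
    """Render a synthetic night into a Recording + ground-truth annotations.

    `noise_sd` maps channel id to additive white-noise standard deviation
    (ECG in mV, acceleration in g, PPG in ADC units).  With
    ``return_truth=True`` a :class:`GroundTruth` carrying the exact
    per-sample parameter trajectories is appended to the return tuple.
    """
    states = dict(STAGE_STATES, **(states or {}))
    for st in states.values():
        st.validate()
    if script is None:
        script = EventScript(duration=300.0)
    noise_sd = noise_sd or {}
    rng = np.random.default_rng(seed)
    truth, motion_amp = _control_series(states, script, max_desat_pct)
    tc = truth.t
    dur = script.duration

    # ---- beat times from the instantaneous heart rate + Gaussian jitter
    # (the control grid is uniform at 10 Hz, so direct indexing replaces
    # interpolation inside the sequential loop)
    ctrl_rate = 10.0
    n_ctrl = tc.size
    hrv_ctrl = np.array([states[s].hrv_sd for s in truth.stage], dtype=float)

    def _at(arr: np.ndarray, t: float) -> float:
        return float(arr[min(int(t * ctrl_rate), n_ctrl - 1)])

    beats = []
    t = 0.1
    while t < dur - 0.05:
        beats.append(t)
        jitter = rng.normal(0.0, _at(hrv_ctrl, t) / 1000.0)
        t += max(0.25, 60.0 / _at(truth.hr, t) + jitter)
    beat_times = np.array(beats)
    truth.beat_times = beat_times

    # ---- ECG (vectorized template placement: fixed-width windows per beat)
    n_ecg = int(round(dur * RATES["ecg"]))
    ecg = np.zeros(n_ecg)
    fs = RATES["ecg"]
    w_ecg = int(0.8 * fs) + 1
    j0s = np.floor((beat_times - 0.35) * fs).astype(int)
    idx = j0s[:, None] + np.arange(w_ecg)[None, :]
    tt = idx / fs - beat_times[:, None]
    vals = _ecg_template(tt)
    ok = (idx >= 0) & (idx < n_ecg)
    np.add.at(ecg, idx[ok], vals[ok])

    # ---- acceleration: gravity + respiration + SCG bursts + movement
    n_acc = int(round(dur * RATES["acc"]))
    fa = RATES["acc"]
    ta = np.arange(n_acc) / fa
    acc = np.zeros((3, n_acc))
    # gravity with 2-s linear cross-fades at position changes
    gvec = np.stack([_GRAVITY[p] for p in truth.position])  # (nc, 3)
    for ax in range(3):
        acc[ax] += np.interp(ta, tc, _smooth_steps(gvec[:, ax], 10.0, 2.0))
    # tidal respiration on the dorso-ventral axis
    rr_inst = np.interp(ta, tc, truth.rr) / 60.0  # Hz
    resp_phase = 2 * np.pi * np.cumsum(rr_inst) / fa
    acc[2] += np.interp(ta, tc, truth.re_amp) * np.sin(resp_phase)
    # SCG bursts (vectorized: one fixed-width window per beat)
    bt_idx = np.minimum((beat_times * 10.0).astype(int), tc.size - 1)
    pep_b = truth.pep[bt_idx] / 1000.0
    lvet_b = truth.lvet[bt_idx] / 1000.0
    amp_b = truth.ao_mag[bt_idx]
    w_scg = int((float(pep_b.max() + lvet_b.max()) + 0.16) * fa) + 1
    j0s = np.floor((beat_times + pep_b - 0.08) * fa).astype(int)
    idx = j0s[:, None] + np.arange(w_scg)[None, :]
    tt = idx / fa - beat_times[:, None]
    seg = (
        _burst(tt, pep_b[:, None], amp_b[:, None])
        + _burst(tt, (pep_b + lvet_b - 0.04)[:, None], 0.35 * amp_b[:, None])
        + _burst(tt, (pep_b + lvet_b)[:, None], 0.6 * amp_b[:, None])
    )
    ok = (idx >= 0) & (idx < n_acc)
    for ax, g in ((2, 1.0), (0, 0.25), (1, 0.15)):
        np.add.at(acc[ax], idx[ok], g * seg[ok])
    # wake movement: band-limited 0.7-3 Hz noise, synthesized at 25 Hz and
    # linearly upsampled (the band is far below that Nyquist)
    mamp = np.interp(ta, tc, motion_amp)
    if np.any(mamp > 0):
        from .preprocess import BandSpec, bandpass

        lo_rate = 25.0
        n_lo = int(round(dur * lo_rate)) + 2
        raw = rng.standard_normal(n_lo)
        mv_lo = bandpass(raw, lo_rate, BandSpec(0.7, 3.0, 2))
        mv_lo /= max(1e-12, np.std(mv_lo))
        mv = np.interp(ta, np.arange(n_lo) / lo_rate, mv_lo)
        for ax, g in enumerate((1.0, 1.0, 0.7)):
            acc[ax] += g * mamp * mv

    # ---- PPG: shared cardiac pulse, ratio-of-ratios encodes SpO2
    n_ppg = int(round(dur * RATES["ppg"]))
    fp = RATES["ppg"]
    tp = np.arange(n_ppg) / fp
    beat_idx = np.interp(tp, beat_times, np.arange(beat_times.size))
    pulse = np.sin(2 * np.pi * beat_idx)  # peak-to-trough 2
    a, b = spo2_calib
    r_t = (a - np.interp(tp, tc, truth.spo2)) / b  # invert spo2 = a - b R
    dc_red, dc_ir = dc_levels
    ac_ir = perfusion_ir * dc_ir / 2.0
    ac_red = r_t * perfusion_ir * dc_red / 2.0
    ppg_ir = dc_ir + ac_ir * pulse
    ppg_red = dc_red + ac_red * pulse

    # ---- additive white noise
    ecg += rng.normal(0, noise_sd.get("ecg", 0.0), n_ecg)
    for ax, name in enumerate(("acc_x", "acc_y", "acc_z")):
        acc[ax] += rng.normal(0, noise_sd.get(name, 0.0), n_acc)
    ppg_red = ppg_red + rng.normal(0, noise_sd.get("ppg_red", 0.0), n_ppg)
    ppg_ir = ppg_ir + rng.normal(0, noise_sd.get("ppg_ir", 0.0), n_ppg)

    rec = Recording(
        channels={
            "ecg": Channel(ecg, RATES["ecg"], "mV"),
            "acc_x": Channel(acc[0], RATES["acc"], "g"),
            "acc_y": Channel(acc[1], RATES["acc"], "g"),
            "acc_z": Channel(acc[2], RATES["acc"], "g"),
            "ppg_red": Channel(ppg_red, RATES["ppg"], "adu"),
            "ppg_ir": Channel(ppg_ir, RATES["ppg"], "adu"),
        },
        meta={"seed": seed, "synthetic": True},
    )
    stages = [
        (30.0 * i, script.stage_at(30.0 * i + 15.0))
        for i in range(int(dur // 30))
    ]
    track = AnnotationTrack(stages=stages, events=script.merged_events())
    if return_truth:
        return rec, track, truth
    return rec, track


def _smooth_steps(x: np.ndarray, ctrl_rate: float, ramp_s: float) -> np.ndarray:
    """Moving-average smoothing of a piecewise-constant control series so
    position flips become `ramp_s`-second cross-fades."""
    w = max(1, int(ramp_s * ctrl_rate))
    kernel = np.ones(w) / w
    pad = np.concatenate([np.full(w, x[0]), x, np.full(w, x[-1])])
    return np.convolve(pad, kernel, mode="same")[w:-w]
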