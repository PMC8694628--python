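"""Synthetic benchmarks: scripted study conditions and their metrics.

Every function here generates its own inputs from the synthetic module,
runs the production pipeline on them, and measures recovery errors or
classification performance.  The sizes are desk-scale study conditions of
this package: a 1-h vitals round-trip record, and an end-to-end benchmark
training on two dense-event 2-h subjects and evaluating on an unseen
subject's 8-h night carrying 25 scripted apnea/hypopnea events.
"""

from __future__ import annotations

import time
from dataclasses import replace

import numpy as np

from . import apnea as apnea_mod
from . import cardiac, mechanics, morse, pipeline, quality, staging, synth
from .io import RunConfig

__all__ = [
    "layer_thickness_sum",
    "epoch_onset_precision",
    "stiffness_oracle_check",
    "morse_recovery",
    "vitals_roundtrip",
    "quality_metrics",
    "end_to_end",
]


# ------------------------------------------------------ analytic quantities


def layer_thickness_sum() -> float:
    """Total thickness (um) of the patch circuit's five thin-film layers."""
    return mechanics.PATCH_STACK.total_thickness_um


def epoch_onset_precision(
    epoch_len: float = 30.0, stride: float = 10.0, grid: int = 10001
) -> float:
    """Worst-case distance (s) from an event onset to the nearest epoch
    boundary under the overlapped epoch scheme."""
    starts = morse.epoch_starts(24 * 3600.0, epoch_len, stride)
    onsets = np.linspace(epoch_len, 3600.0, grid)
    d = np.min(np.abs(onsets[:, None] - starts[None, : int(400)]), axis=1)
    return float(d.max())


def stiffness_oracle_check(seed: int = 0, n_cases: int = 100) -> dict:
    """Transformed-section closed form vs brute-force integration on random
    laminates, plus the patch-stack numbers (both formula variants)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        n_layers = int(rng.integers(1, 7))
        layers = tuple(
            mechanics.Layer(float(rng.uniform(0.5, 20.0)), float(rng.uniform(1.0, 200.0)))
            for _ in range(n_layers)
        )
        spec = mechanics.LaminateSpec(
            layers=layers,
            width_mm=float(rng.uniform(5, 50)),
            length_mm=float(rng.uniform(10, 100)),
            ref_modulus_gpa=float(layers[0].modulus_gpa),
        )
        i_closed = mechanics.transformed_inertia(spec)
        _, i_oracle = mechanics.integrate_section(spec)
        worst = max(worst, abs(i_closed - i_oracle) / i_oracle)
    stack = mechanics.PATCH_STACK
    _, i_oracle = mechanics.integrate_section(stack)
    return {
        "max_rel_err": worst,
        "patch_k_n_per_m": mechanics.bending_stiffness(stack),
        "patch_k_as_printed_variant": mechanics.bending_stiffness(stack, as_printed=True),
        "patch_inertia_oracle_m4": i_oracle,
        "n_cases": n_cases,
    }


# --------------------------------------------------------- morse benchmarks


def morse_recovery(seed: int = 0) -> dict:
    """Injected-element parameter recovery and the zeta_max oracle check."""
    rng = np.random.default_rng(seed)
    rate, n = 100.0, 6000
    params = morse.MorseParams.from_band(0.1, 10.0, voices=8)
    grid_step = n and 1.0 / rate
    # zero-noise single-element recovery
    c_errs, t_errs, rho_steps = [], [], []
    for _ in range(8):
        c = rng.uniform(0.5, 2.0) * np.exp(1j * rng.uniform(-np.pi, np.pi))
        t0 = rng.uniform(20.0, 40.0)
        rho = rng.uniform(0.15, 0.8)
        x = morse.inject_morse_element(np.zeros(n), rate, c, t0, rho)
        scal = morse.cwt(x, rate, params)
        ev = morse.infer_events(morse.transform_maxima(scal, threshold=0.05)[:1], params)[0]
        c_errs.append(abs(abs(ev.c) - abs(c)) / abs(c))
        t_errs.append(abs(ev.t - t0))
        rho_steps.append(
            abs(np.log(ev.rho / rho)) / np.log(params.scales[1] / params.scales[0])
        )
    # zeta_max closed form vs numeric maximization of |zeta|
    zeta_errs = []
    for beta, mu, gamma in ((2.0, 2.0, 3.0), (3.0, 2.0, 3.0), (3.0, 3.0, 2.0)):
        closed = morse.zeta_max(beta, mu, gamma)
        rs = np.geomspace(0.2, 5.0, 201)
        taus = np.linspace(-3.0, 3.0, 161)
        brute = max(
            float(np.abs(morse.zeta(taus, r, beta, mu, gamma)).max()) for r in rs
        )
        zeta_errs.append(abs(closed - brute) / brute)
    return {
        "c_mag_err_pct": 100.0 * float(np.max(c_errs)),
        "t_err_grid_steps": float(np.max(t_errs)) / grid_step,
        "rho_err_scale_steps": float(np.max(rho_steps)),
        "zeta_max_err_pct": 100.0 * float(np.max(zeta_errs)),
    }


# --------------------------------------------------------- vitals round trip


def vitals_roundtrip(seed: int = 0, duration: float = 3600.0) -> dict:
    """1-h zero-noise record: recovery errors for every SCOPER vital.

    One physiological operating point (HR 62, RR 14, PEP 90 ms, LVET
    300 ms, SpO2 97 %) held across four body-position segments, plus four
    scripted desaturation events of 5/15/25/35 % depth.
    """
    base = synth.PhysioState(hr=62, hrv_sd=20, rr=14, re_amp=0.025, spo2=97,
                             pep=90, lvet=300, ao_mag=0.04, motion_amp=0.0)
    states = {
        "wake": replace(base, position="supine"),
        "light": replace(base, position="left"),
        "deep": replace(base, position="prone"),
        "rem": replace(base, position="right"),
    }
    seg = duration / 4.0
    plan = [(0.0, "wake"), (seg, "light"), (2 * seg, "deep"), (3 * seg, "rem")]
    depths = (5.0, 15.0, 25.0, 35.0)
    # long events so the first-order desaturation approaches its cap
    events = [
        (300.0 + i * 800.0, 120.0, "apnea", d / 35.0) for i, d in enumerate(depths)
    ]
    script = synth.EventScript(duration=duration, events=events, stage_plan=plan)
    rec, track, truth = synth.generate_recording(
        states=states, script=script, seed=seed, return_truth=True
    )
    cfg = RunConfig(seed=seed)
    bundle = pipeline.compute_vitals(rec, cfg, build_features=False)
    vit = bundle.vitals
    t = vit["time"].to_numpy()
    # mask epochs overlapping events or their 15-s sympathetic aftermath
    clean = np.ones(t.size, dtype=bool)
    for onset, dur, _, _ in events:
        clean &= ~((t > onset - 45.0) & (t < onset + dur + 60.0))
    # position transitions are also excluded from the steady-state checks
    for edge in (seg, 2 * seg, 3 * seg):
        clean &= np.abs(t - edge) > 45.0
    med = lambda col: float(np.nanmedian(vit[col][clean]))
    hr_err = abs(med("hr") - base.hr)
    rr_err = abs(med("rr") - base.rr)
    spo2_err = abs(med("spo2") - base.spo2)
    pep_err = abs(med("pep") - base.pep)
    lvet_err = abs(med("lvet") - base.lvet)
    re_err = abs(med("re") - base.re_amp)
    # position labels per segment (exclude the 2-s crossfade windows)
    pos = bundle.positions
    pos_ok = []
    for (start, stage), want in zip(plan, ("supine", "left", "prone", "right")):
        sel = (pos["time"] >= start + 20) & (pos["time"] < start + seg - 20)
        labels = pos["position"][sel]
        pos_ok.append(bool((labels == want).all()))
    # desaturation depths: truth nadir vs estimated nadir per event
    sp_t = vit["time"].to_numpy()
    desat_errs = []
    for (onset, dur, _, sev), depth in zip(events, depths):
        w0, w1 = onset, onset + dur + 40.0
        truth_nadir = float(truth.spo2[(truth.t >= w0) & (truth.t < w1)].min())
        est = vit["spo2"][(sp_t >= w0) & (sp_t < w1)]
        est_nadir = float(np.nanmin(est))
        desat_errs.append(abs(est_nadir - truth_nadir))
    return {
        "hr_err_bpm": hr_err,
        "rr_err_bpm": rr_err,
        "spo2_err_pct": spo2_err,
        "pep_err_ms": pep_err,
        "lvet_err_ms": lvet_err,
        "re_err_g": re_err,
        "positions_exact": all(pos_ok),
        "desat_err_pct_max": float(np.max(desat_errs)),
        "desat_depths_pct": list(depths),
    }


# ------------------------------------------------------------ quality bench


def quality_metrics(seed: int = 0) -> dict:
    """Periodicity and DTW repeatability on constructed fixtures."""
    rng = np.random.default_rng(seed)
    rate = 128.0
    template = synth._ecg_template(np.arange(-0.4, 0.6, 1.0 / rate))
    periodic = np.tile(template, 40)
    period = template.size / rate
    beats = cardiac.BeatTable(
        np.arange(40) * period + 0.4, np.ones(40)
    )
    p_per = quality.periodicity(periodic, rate, beats)["one_beat"]
    noise = rng.standard_normal(periodic.size)
    p_noise = quality.periodicity(noise, rate, beats)["one_beat"]
    beats_m = np.tile(template, (20, 1))
    d_ident = quality.dtw_repeatability(beats_m)
    d_by_sigma = []
    for s in (0.0, 0.05, 0.1, 0.2):
        noisy = beats_m + rng.normal(0, s, beats_m.shape)
        d_by_sigma.append(quality.dtw_repeatability(noisy))
    return {
        "periodicity_periodic": float(p_per),
        "periodicity_noise": float(p_noise),
        "dtw_identical": float(d_ident),
        "dtw_by_sigma": [float(v) for v in d_by_sigma],
        "dtw_monotone": bool(np.all(np.diff(d_by_sigma) >= -1e-12)),
    }


# --------------------------------------------------------------- end to end


def _night_script(
    duration: float, n_events: int, rng: np.random.Generator, lead_in: float = 900.0
) -> synth.EventScript:
    """Sleep-architecture plan plus scripted events, avoiding wake."""
    plan: list[tuple[float, str]] = [(0.0, "wake")]
    t = lead_in
    cycle = [("light", 1500.0), ("deep", 1200.0), ("rem", 900.0)]
    i = 0
    while t < duration - 600.0:
        stage, dur = cycle[i % 3]
        plan.append((t, stage))
        t += dur
        i += 1
    plan.append((duration - 300.0, "wake"))
    # events uniformly over the sleep period with >= 90-s spacing
    onsets: list[float] = []
    tries = 0
    while len(onsets) < n_events and tries < 20000:
        tries += 1
        cand = float(rng.uniform(lead_in + 60.0, duration - 400.0))
        if all(abs(cand - o) >= 90.0 for o in onsets):
            onsets.append(cand)
    events = []
    for o in sorted(onsets):
        dur = float(rng.uniform(15.0, 45.0))
        sev = float(rng.uniform(0.5, 1.0))
        typ = "apnea" if sev > 0.8 else "hypopnea"
        events.append((o, dur, typ, sev))
    return synth.EventScript(duration=duration, events=events, stage_plan=plan)


NIGHT_NOISE = {
    "ecg": 0.02, "acc_x": 0.003, "acc_y": 0.003, "acc_z": 0.003,
    "ppg_red": 5.0, "ppg_ir": 5.0,
}


def end_to_end(
    seed: int = 0,
    train_hours: float = 2.0,
    n_train_subjects: int = 2,
    train_events_each: int = 50,
    test_hours: float = 8.0,
    n_events_test: int = 25,
    raster: int = 32,
    cnn_epochs: int = 25,
) -> dict:
    """Unseen-subject benchmark.

    The stager, the residual CNN and the parametric gate are trained on a
    small corpus of symptomatic synthetic subjects (dense event schedules,
    so every stage x severity combination is represented) and evaluated on
    a held-out subject's full 8-h night with 25 scripted events.
    """
    t_start = time.time()
    rng = np.random.default_rng(seed)
    cfg = RunConfig(seed=seed, raster=raster)

    def _subject(sub_seed: int, hours: float, n_events: int, lead_in: float = 900.0):
        script = _night_script(hours * 3600.0, n_events, rng, lead_in=lead_in)
        rec, track = synth.generate_recording(
            script=script, noise_sd=NIGHT_NOISE, seed=sub_seed
        )
        bundle = pipeline.compute_vitals(rec, cfg)
        imgs = pipeline.scalogram_stack(bundle, cfg, raster=raster)
        labels = apnea_mod.epoch_labels(track.events, bundle.epoch_starts_stride)
        return script, track, bundle, imgs, labels

    train = [
        _subject(seed + 1 + k, train_hours, train_events_each, lead_in=300.0)
        for k in range(n_train_subjects)
    ]
    tr_track, tr_bundle = train[0][1], train[0][2]
    tr_imgs = np.concatenate([t[3] for t in train])
    tr_labels = np.concatenate([t[4] for t in train])
    te_script, te_track, te_bundle, te_imgs, te_labels = _subject(
        seed + 100, test_hours, n_events_test
    )

    # ---- sleep stager (4-class training, merged 3-class scoring)
    tr_stages = tr_track.stage_labels(tr_bundle.n_epochs)
    stager = staging.train_stager(tr_bundle.features, tr_stages, seed=seed)
    te_feats = staging.EpochFeatureMatrix(
        values=pipeline._renorm(te_bundle, stager),
        names=te_bundle.features.names,
        norm_params=stager.norm_params,
        unscorable=te_bundle.features.unscorable,
        raw=te_bundle.features.raw,
    )
    hyp = staging.predict_hypnogram(stager, te_feats)
    te_stages = te_track.stage_labels(te_bundle.n_epochs)
    merged_true = ["nrem" if s in ("light", "deep") else s for s in te_stages]
    stage_acc = float(np.mean([a == b for a, b in zip(hyp.labels, merged_true)]))

    # ---- apnea CNN + parametric gate
    model = apnea_mod.build_rcnn(depth_blocks=cfg.cnn_blocks, raster=raster, seed=seed)
    apnea_mod.train_apnea(model, tr_imgs, tr_labels, epochs=cnn_epochs)
    gate_feats = np.concatenate([pipeline.gate_feature_matrix(t[2]) for t in train])
    gate = apnea_mod.RusBoostGate(seed=seed).fit(gate_feats, tr_labels)
    conf_raw = model.predict(te_imgs)
    thr = 0.4
    conf, _ = apnea_mod.parametric_gate(
        conf_raw, pipeline.gate_feature_matrix(te_bundle),
        quality_accept=pipeline.stride_quality_accept(te_bundle), gate=gate,
        mode="veto", threshold=thr, margin=0.3,
    )
    pred = conf >= thr
    tp = int(np.sum(pred & (te_labels == 1)))
    fp = int(np.sum(pred & (te_labels == 0)))
    fn = int(np.sum(~pred & (te_labels == 1)))
    sens = tp / max(tp + fn, 1)
    prec = tp / max(tp + fp, 1)
    # gate ablation + pass-through rate on true detections
    true_det = (conf_raw >= thr) & (te_labels == 1)
    gate_pass = float(np.mean(conf[true_det] >= thr)) if true_det.any() else 1.0
    fp_ungated = int(np.sum((conf_raw >= thr) & (te_labels == 0)))

    # ---- event post-processing and onset localization
    tst = 30.0 * sum(1 for l in hyp.labels if l != "wake")
    ev_list = apnea_mod.postprocess_events(
        te_bundle.epoch_starts_stride, conf, threshold=thr, total_sleep_time=tst,
        refine_onsets=True,
    )
    onset_errs = []
    for onset, offset, _ in te_track.events:
        if ev_list.events:
            onset_errs.append(min(abs(onset - e[0]) for e in ev_list.events))
    sep_ok = all(
        b[0] - a[0] >= 10.0 for a, b in zip(ev_list.events, ev_list.events[1:])
    )
    return {
        "sensitivity": float(sens),
        "precision": float(prec),
        "staging_accuracy": stage_acc,
        "gate_true_pass": gate_pass,
        "fp_ungated": fp_ungated,
        "fp_gated": fp,
        "n_detected_events": len(ev_list.events),
        "n_true_events": len(te_track.events),
        "ahi": ev_list.ahi,
        "onset_err_max_s": float(np.max(onset_errs)) if onset_errs else float("nan"),
        "separation_invariant_ok": bool(sep_ok),
        "rejection_fraction": te_bundle.rejection_fraction,
        "runtime_s": time.time() - t_start,
    }
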