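"""End-to-end pipeline: recording -> vitals, quality, scalograms, staging,
events.

Stages only communicate through the declared types (Recording, BeatTable,
feature matrices, scalogram image stacks).  Each modality fails soft: a
dead or absent channel disables its own metrics and leaves the rest of the
run intact.  All outputs embed the RunConfig hash and seed so reruns are
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import apnea as apnea_mod
from . import cardiac, morse, oximetry, quality, resp_position, staging
from .io import AnnotationTrack, Recording, RunConfig, load_recording
from .preprocess import BandSpec, bandpass, resample

log = logging.getLogger("scoper")

#: rate to which the wide-band SCG is decimated for scalogram analysis
SCALOGRAM_RATE = 64.0


@dataclass
class VitalsBundle:
    """Everything the classifiers and writers need from one recording."""

    vitals: pd.DataFrame          # per-30-s-epoch vitals table
    quality: pd.DataFrame         # per-epoch quality metrics + accept mask
    beats: cardiac.BeatTable | None
    positions: pd.DataFrame
    n_epochs: int
    epoch_starts_stride: np.ndarray     # 10-s stride epoch grid for apnea
    scg_scalo: np.ndarray | None        # wide-band SCG at SCALOGRAM_RATE
    features: staging.EpochFeatureMatrix | None
    rejection_fraction: float
    duration: float


def compute_vitals(
    rec: Recording, cfg: RunConfig | None = None, build_features: bool = True
) -> VitalsBundle:
    """Run the deterministic signal chain on one recording."""
    cfg = cfg or RunConfig()
    duration = rec.duration
    n_epochs = int(duration // cfg.epoch_len)
    epoch_t = np.arange(n_epochs) * cfg.epoch_len + cfg.epoch_len / 2

    # ---- cardiac chain
    beats = None
    hr_df = pd.DataFrame(columns=["time", "hr", "sdnn", "rmssd"])
    fid_rows = []
    scg = None
    if "ecg" in rec:
        ecg = bandpass(rec["ecg"].samples, rec["ecg"].rate, BandSpec(*cfg.bands["ecg"]))
        beats = cardiac.detect_r_peaks(ecg, rec["ecg"].rate)
        if len(beats) >= 2:
            hr_df = cardiac.hr_hrv_series(beats, cfg.epoch_len, cfg.epoch_len)
    if "acc_z" in rec and beats is not None and len(beats) >= 3:
        fa = rec["acc_z"].rate
        scg = bandpass(rec["acc_z"].samples, fa, BandSpec(*cfg.bands["scg"]))
        for t0 in np.arange(0.0, duration - 60.0 + 1e-9, 60.0):
            sel = (beats.r_times >= t0) & (beats.r_times < t0 + 60.0)
            if sel.sum() < 3:
                fid_rows.append((t0 + 30.0, np.nan, np.nan, np.nan))
                continue
            sub = cardiac.BeatTable(beats.r_times[sel], beats.quality[sel])
            try:
                ens = cardiac.segment_and_ensemble(scg, fa, sub, window=0.5)
                fid = cardiac.detect_fiducials(
                    ens, ao_window=cfg.ao_window, ac_window=cfg.ac_window
                )
                fid_rows.append(
                    (t0 + 30.0, fid.pep or np.nan, fid.lvet or np.nan,
                     fid.ao_mag or np.nan)
                )
            except ValueError:
                fid_rows.append((t0 + 30.0, np.nan, np.nan, np.nan))
    fid_df = pd.DataFrame(fid_rows, columns=["time", "pep", "lvet", "ao_mag"])

    # ---- kinetic energy
    ke = None
    if "acc_z" in rec:
        ke_t, ke_m = cardiac.kinetic_energy_bands(rec["acc_z"].samples, rec["acc_z"].rate)
        ke = (ke_t + 2.5, ke_m)

    # ---- oximetry (fail-soft when PPG absent)
    sp_df = pd.DataFrame(columns=["time", "spo2"])
    if "ppg_red" in rec and "ppg_ir" in rec:
        sp = oximetry.spo2_series(
            rec["ppg_red"].samples, rec["ppg_ir"].samples, rec["ppg_red"].rate,
            calib=cfg.spo2_calib,
        )
        sp_df = pd.DataFrame(
            {"time": sp.times, "spo2": np.where(sp.valid, sp.spo2, np.nan)}
        )
    else:
        log.warning("PPG channels missing: SpO2 marked missing")

    # ---- respiration and position
    re_df = pd.DataFrame(columns=["time", "re"])
    rr_df = pd.DataFrame(columns=["time", "rr"])
    pos_df = pd.DataFrame(columns=["time", "position"])
    acti = None
    if "acc_z" in rec:
        fa = rec["acc_z"].rate
        re_df, re_wave = resp_position.respiratory_effort(rec["acc_z"].samples, fa)
        rr_df = resp_position.respiration_rate(re_wave, fa, window=60.0, step=30.0)
        acc3 = np.vstack([
            rec[f"acc_{ax}"].samples for ax in "xyz" if f"acc_{ax}" in rec
        ])
        if acc3.shape[0] == 3:
            pos_df = resp_position.body_position(acc3, fa)
            acti = staging.actigraphy_series(acc3, fa, n_epochs, cfg.epoch_len)

    # ---- per-epoch vitals table
    def _to_epochs(df: pd.DataFrame, col: str) -> np.ndarray:
        out = np.full(n_epochs, np.nan)
        if df.empty:
            return out
        t = df["time"].to_numpy(dtype=float)
        v = df[col].to_numpy(dtype=float)
        for i, tc in enumerate(epoch_t):
            sel = np.abs(t - tc) <= cfg.epoch_len
            if np.any(np.isfinite(v[sel])):
                out[i] = np.nanmean(v[sel])
        return out

    def _to_epochs_min(df: pd.DataFrame, col: str) -> np.ndarray:
        out = np.full(n_epochs, np.nan)
        if df.empty:
            return out
        t = df["time"].to_numpy(dtype=float)
        v = df[col].to_numpy(dtype=float)
        for i, tc in enumerate(epoch_t):
            sel = np.abs(t - tc) <= cfg.epoch_len / 2
            if np.any(np.isfinite(v[sel])):
                out[i] = np.nanmin(v[sel])
        return out

    vit = pd.DataFrame({"time": epoch_t})
    for src, col in ((hr_df, "hr"), (hr_df, "sdnn"), (hr_df, "rmssd"),
                     (fid_df, "pep"), (fid_df, "lvet"), (fid_df, "ao_mag"),
                     (rr_df, "rr"), (re_df, "re"), (sp_df, "spo2")):
        vit[col] = _to_epochs(src, col)
    # event detection keys on transients, so the within-epoch minima of the
    # fast series are carried alongside the smoothed means
    vit["spo2_min"] = _to_epochs_min(sp_df, "spo2")
    vit["re_min"] = _to_epochs_min(re_df, "re")

    # ---- quality metrics per epoch
    per = np.full(n_epochs, np.nan)
    rep = np.full(n_epochs, np.nan)
    if beats is not None and len(beats) >= 3 and "ecg" in rec:
        fe = rec["ecg"].rate
        for i in range(n_epochs):
            j0 = int(i * cfg.epoch_len * fe)
            j1 = int((i + 1) * cfg.epoch_len * fe)
            sel = (beats.r_times >= i * cfg.epoch_len) & (
                beats.r_times < (i + 1) * cfg.epoch_len
            )
            if sel.sum() >= 3:
                sub = cardiac.BeatTable(
                    beats.r_times[sel] - i * cfg.epoch_len, beats.quality[sel]
                )
                per[i] = quality.periodicity(ecg[j0:j1], fe, sub)["one_beat"]
    if scg is not None and beats is not None and len(beats) >= 3:
        fa = rec["acc_z"].rate
        for t0 in np.arange(0.0, duration - 60.0 + 1e-9, 60.0):
            sel = (beats.r_times >= t0) & (beats.r_times < t0 + 60.0)
            if sel.sum() < 3:
                continue
            sub = cardiac.BeatTable(beats.r_times[sel], beats.quality[sel])
            try:
                ens = cardiac.segment_and_ensemble(scg, fa, sub, window=0.5)
            except ValueError:
                continue
            score = quality.dtw_repeatability(ens.matrix[:20])
            e0 = int(t0 // cfg.epoch_len)
            for e in range(e0, min(e0 + 2, n_epochs)):
                rep[e] = score
    qual = pd.DataFrame({"time": epoch_t, "periodicity": per, "repeatability": rep})
    accept, frac = quality.quality_gate(qual)
    qual["accept"] = accept

    # ---- wide-band SCG for scalograms
    scg_scalo = None
    if "acc_z" in rec:
        fa = rec["acc_z"].rate
        wide = bandpass(rec["acc_z"].samples, fa, BandSpec(*cfg.bands["scg_wide"]))
        scg_scalo = resample(wide, fa, SCALOGRAM_RATE)

    features = None
    if build_features and n_epochs >= 2:
        features = staging.build_epoch_features(
            vit, ke, acti, n_epochs, cfg.epoch_len
        )

    return VitalsBundle(
        vitals=vit,
        quality=qual,
        beats=beats,
        positions=pos_df,
        n_epochs=n_epochs,
        epoch_starts_stride=morse.epoch_starts(duration, cfg.epoch_len, cfg.epoch_stride),
        scg_scalo=scg_scalo,
        features=features,
        rejection_fraction=frac,
        duration=duration,
    )


def scalogram_stack(
    bundle: VitalsBundle, cfg: RunConfig | None = None, raster: int | None = None
) -> np.ndarray:
    """Element-analysis scalogram image per stride epoch."""
    cfg = cfg or RunConfig()
    raster = raster or cfg.raster
    if bundle.scg_scalo is None:
        raise ValueError("no SCG channel: cannot build scalograms")
    params = morse.MorseParams.from_band(
        0.1, 24.0, beta=cfg.morse["beta"], mu=cfg.morse["mu"], gamma=cfg.morse["gamma"]
    )
    imgs = np.empty((bundle.epoch_starts_stride.size, raster, raster), dtype=np.float32)
    for i, t0 in enumerate(bundle.epoch_starts_stride):
        imgs[i] = morse.scalogram_image(
            bundle.scg_scalo, SCALOGRAM_RATE, (float(t0), cfg.epoch_len),
            params=params, raster=(raster, raster),
        )
    return imgs


def save_scalograms(
    imgs: np.ndarray, path: str | Path, previews: int = 0
) -> None:
    """Persist a scalogram image stack as an NPZ container, optionally with
    PNG previews of the first `previews` epochs next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, images=imgs)
    if previews:
        from matplotlib import cm
        from matplotlib.image import imsave

        for i in range(min(previews, imgs.shape[0])):
            imsave(
                path.with_suffix(f".epoch{i:04d}.png"),
                imgs[i][::-1], cmap=cm.magma, vmin=0.0, vmax=1.0,
            )


def gate_feature_matrix(bundle: VitalsBundle) -> np.ndarray:
    """Per-stride-epoch parametric features for the RUS-boost gate.

    Each stride epoch aggregates the vitals/quality series over its full
    [t0, t0+30 s) window with the extremum that an event would drive
    (minimum for periodicity/PEP/LVET/RR, maximum for HR/repeatability),
    so an epoch overlapping an event carries the event's signature
    regardless of where in the window it falls.  SpO2 and respiratory
    effort enter relative to the subject's own baseline — desaturation
    depth below the record median and RE fraction of the record median —
    which transfers across subjects with different operating points.
    """
    starts = bundle.epoch_starts_stride
    cols = {"periodicity": bundle.quality["periodicity"],
            "repeatability": bundle.quality["repeatability"]}
    maximize = {"hr", "repeatability"}
    out = np.zeros((starts.size, len(apnea_mod.GATE_FEATURES)))
    epoch_t = bundle.vitals["time"].to_numpy(dtype=float)

    def _window_agg(name: str, source: str) -> np.ndarray:
        src = cols[source] if source in cols else bundle.vitals[source]
        v = np.asarray(src, dtype=float)
        good = np.isfinite(v)
        if good.sum() == 0:
            return np.zeros(starts.size)
        vv = np.where(good, v, float(np.nanmedian(v)))
        agg = np.maximum if name in maximize else np.minimum
        res = np.empty(starts.size)
        for i, t0 in enumerate(starts):
            sel = (epoch_t > t0 - 15.0) & (epoch_t < t0 + 45.0)
            res[i] = agg.reduce(vv[sel]) if np.any(sel) else float(np.median(vv))
        return res

    for j, name in enumerate(apnea_mod.GATE_FEATURES):
        if name == "spo2_drop":
            base = float(np.nanmedian(bundle.vitals["spo2_min"])) if np.any(
                np.isfinite(bundle.vitals["spo2_min"])
            ) else 0.0
            out[:, j] = base - _window_agg(name, "spo2_min")
        elif name == "re_ratio":
            base = float(np.nanmedian(bundle.vitals["re_min"])) or 1.0
            if not np.isfinite(base) or base == 0.0:
                base = 1.0
            out[:, j] = _window_agg(name, "re_min") / base
        else:
            out[:, j] = _window_agg(name, name)
    return out


def stride_quality_accept(bundle: VitalsBundle) -> np.ndarray:
    """Quality-gate accept mask resampled onto the 10-s stride grid."""
    acc = bundle.quality["accept"].to_numpy(dtype=bool)
    epoch_t = bundle.vitals["time"].to_numpy(dtype=float)
    out = np.ones(bundle.epoch_starts_stride.size, dtype=bool)
    for i, t0 in enumerate(bundle.epoch_starts_stride):
        sel = np.abs(epoch_t - (t0 + 15.0)) <= 30.0
        if np.any(sel):
            out[i] = bool(np.all(acc[sel]))
    return out


def run_pipeline(
    source: Recording | str | Path,
    cfg: RunConfig | None = None,
    out_dir: str | Path | None = None,
    stager: staging.StagerModel | None = None,
    apnea_model=None,
    gate: apnea_mod.RusBoostGate | None = None,
) -> dict:
    """Full run: vitals + quality always; hypnogram and events when the
    corresponding trained models are supplied.  Writes vitals.csv,
    quality.csv, hypnogram.csv, events.csv and summary.json into
    `out_dir` when given; returns the summary dict."""
    cfg = cfg or RunConfig()
    rec = source if isinstance(source, Recording) else load_recording(source)
    bundle = compute_vitals(rec, cfg)
    summary: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "duration_s": bundle.duration,
        "n_epochs": bundle.n_epochs,
        "rejection_fraction": bundle.rejection_fraction,
    }
    hyp = None
    if stager is not None and bundle.features is not None:
        feats = staging.EpochFeatureMatrix(
            values=_renorm(bundle, stager),
            names=bundle.features.names,
            norm_params=stager.norm_params,
            unscorable=bundle.features.unscorable,
        )
        hyp = staging.predict_hypnogram(stager, feats)
        tst = 30.0 * sum(1 for l in hyp.labels if l != "wake")
        summary["total_sleep_time_s"] = tst
    events = None
    if apnea_model is not None and bundle.scg_scalo is not None:
        imgs = scalogram_stack(bundle, cfg, raster=apnea_model.raster)
        conf = apnea_model.predict(imgs)
        if gate is not None:
            conf, _ = apnea_mod.parametric_gate(
                conf, gate_feature_matrix(bundle),
                quality_accept=stride_quality_accept(bundle), gate=gate,
            )
        tst = summary.get("total_sleep_time_s", bundle.duration)
        events = apnea_mod.postprocess_events(
            bundle.epoch_starts_stride, conf,
            epoch_len=cfg.epoch_len, stride=cfg.epoch_stride,
            total_sleep_time=tst,
        )
        summary["n_events"] = len(events.events)
        summary["ahi"] = events.ahi
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.vitals.assign(config_hash=cfg.config_hash(), seed=cfg.seed).to_csv(
            out / "vitals.csv", index=False
        )
        bundle.quality.to_csv(out / "quality.csv", index=False)
        if hyp is not None:
            pd.DataFrame({
                "epoch_start": np.arange(len(hyp.labels)) * cfg.epoch_len,
                "label": hyp.labels,
                "p_wake": hyp.proba4[:, 0], "p_light": hyp.proba4[:, 1],
                "p_deep": hyp.proba4[:, 2], "p_rem": hyp.proba4[:, 3],
            }).to_csv(out / "hypnogram.csv", index=False)
        if events is not None:
            pd.DataFrame(
                events.events, columns=["onset", "offset", "confidence"]
            ).to_csv(out / "events.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _renorm(bundle: VitalsBundle, stager: staging.StagerModel) -> np.ndarray:
    """Apply the stager's training-time min-max params to this recording's
    raw (pre-normalization) features."""
    raw = bundle.features.raw
    tmins, tmaxs = stager.norm_params
    tspan = np.where(tmaxs - tmins <= 0, 1.0, tmaxs - tmins)
    return (raw - tmins) / tspan
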