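"""Epoch feature assembly and feedforward sleep staging.

Per 30-s epoch, summary statistics of the cardiorespiratory vitals (HR,
HRV, RR, RE, SpO2, PEP, LVET, |AO|), the band-limited cardiac
kinetic-energy means and an actigraphy power feature are assembled —
including a +-1-epoch temporal context — min-max normalized, and fed to a
single-hidden-layer FFNN (120 sigmoid units, softmax output over the four
scored classes wake / light / deep / REM) trained with conjugate-gradient
backpropagation.  At prediction time light and deep are pooled into one
NREM class: staging wake vs light sleep is a notoriously soft boundary and
pooling avoids forcing a false dilemma on the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import FeedForwardNet
from .preprocess import BandSpec, bandpass, min_max_normalize

__all__ = [
    "STAGES4",
    "STAGES3",
    "EpochFeatureMatrix",
    "Hypnogram",
    "actigraphy_series",
    "build_epoch_features",
    "train_stager",
    "predict_hypnogram",
    "fourfold_cv",
]

STAGES4 = ("wake", "light", "deep", "rem")
STAGES3 = ("wake", "nrem", "rem")


@dataclass
class EpochFeatureMatrix:
    values: np.ndarray            # epochs x features, min-max normalized
    names: list[str]
    norm_params: tuple[np.ndarray, np.ndarray]
    unscorable: np.ndarray        # bool per epoch
    epoch_len: float = 30.0
    raw: np.ndarray | None = None  # pre-normalization values (imputed)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if self.values.shape[1] != len(self.names):
            raise ValueError("feature count mismatch")


@dataclass
class Hypnogram:
    """Per-epoch merged labels and the underlying 4-class probabilities."""

    labels: list[str]
    proba4: np.ndarray            # epochs x 4 over STAGES4
    carried: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if not np.allclose(self.proba4.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probabilities must sum to 1 per epoch")
        if np.any(self.proba4 < -1e-9):
            raise ValueError("probabilities must be nonnegative")
        if self.carried is None:
            self.carried = np.zeros(len(self.labels), dtype=bool)

    @property
    def proba3(self) -> np.ndarray:
        """Merged probabilities over (wake, nrem, rem); pooling light+deep
        leaves the wake and REM probabilities untouched."""
        p = self.proba4
        return np.column_stack([p[:, 0], p[:, 1] + p[:, 2], p[:, 3]])


def actigraphy_series(
    acc: np.ndarray, rate: float, n_epochs: int, epoch_len: float = 30.0
) -> np.ndarray:
    """Gross-movement feature: 0.7-3 Hz band power of the acceleration
    magnitude per epoch."""
    mag = np.linalg.norm(np.asarray(acc, dtype=float), axis=0)
    band = bandpass(mag, rate, BandSpec(0.7, 3.0, 2))
    out = np.zeros(n_epochs)
    for i in range(n_epochs):
        j0 = int(i * epoch_len * rate)
        j1 = int((i + 1) * epoch_len * rate)
        seg = band[j0:j1]
        out[i] = float(np.mean(seg**2)) if seg.size else np.nan
    return out


def _epoch_stats(series_t: np.ndarray, series_v: np.ndarray, t0: float, t1: float):
    sel = (series_t >= t0) & (series_t < t1)
    v = series_v[sel]
    v = v[np.isfinite(v)]
    if v.size == 0:
        return (np.nan,) * 4
    return (float(v.mean()), float(v.std()), float(v.min()), float(v.max()))


def build_epoch_features(
    vitals: pd.DataFrame,
    ke: tuple[np.ndarray, np.ndarray] | None,
    actigraphy: np.ndarray | None,
    n_epochs: int,
    epoch_len: float = 30.0,
    norm_params: tuple[np.ndarray, np.ndarray] | None = None,
) -> EpochFeatureMatrix:
    """Assemble the per-epoch feature matrix.

    `vitals` has a ``time`` column plus one column per vital; for each
    epoch, mean/sd/min/max are computed over the epoch itself and over the
    3-epoch context window (epoch plus both neighbors).  KE band means and
    the actigraphy power are appended.  Missing values are imputed by
    linear interpolation across epochs; an epoch with more than 50 %
    missing raw features is flagged unscorable.
    """
    cols = [c for c in vitals.columns if c != "time"]
    tv = vitals["time"].to_numpy(dtype=float)
    names: list[str] = []
    raw = np.full((n_epochs, 0), np.nan)
    blocks = []
    for c in cols:
        vv = vitals[c].to_numpy(dtype=float)
        block = np.full((n_epochs, 8), np.nan)
        for i in range(n_epochs):
            t0, t1 = i * epoch_len, (i + 1) * epoch_len
            block[i, :4] = _epoch_stats(tv, vv, t0, t1)
            block[i, 4:] = _epoch_stats(
                tv, vv, (i - 1) * epoch_len, (i + 2) * epoch_len
            )
        blocks.append(block)
        names += [f"{c}_{s}" for s in ("mean", "sd", "min", "max")]
        names += [f"{c}_ctx_{s}" for s in ("mean", "sd", "min", "max")]
    if ke is not None:
        ke_t, ke_m = ke
        block = np.full((n_epochs, ke_m.shape[1]), np.nan)
        for i in range(n_epochs):
            sel = (ke_t >= i * epoch_len) & (ke_t < (i + 1) * epoch_len)
            if np.any(sel):
                block[i] = ke_m[sel].mean(axis=0)
        blocks.append(block)
        names += [f"ke_band{j}" for j in range(ke_m.shape[1])]
    if actigraphy is not None:
        blocks.append(np.asarray(actigraphy, dtype=float)[:n_epochs, None])
        names += ["actigraphy"]
    raw = np.hstack(blocks)
    missing_frac = np.mean(~np.isfinite(raw), axis=1)
    unscorable = missing_frac > 0.5
    # neighbor interpolation per feature column
    for j in range(raw.shape[1]):
        col = raw[:, j]
        bad = ~np.isfinite(col)
        if bad.all():
            raw[:, j] = 0.0
        elif bad.any():
            idx = np.arange(n_epochs)
            raw[bad, j] = np.interp(idx[bad], idx[~bad], col[~bad])
    normed, params = min_max_normalize(raw, norm_params)
    return EpochFeatureMatrix(
        values=normed, names=names, norm_params=params, unscorable=unscorable,
        epoch_len=epoch_len, raw=raw,
    )


@dataclass
class StagerModel:
    net: FeedForwardNet
    norm_params: tuple[np.ndarray, np.ndarray]
    feature_names: list[str]
    seed: int


def train_stager(
    features: EpochFeatureMatrix,
    labels: list[str] | np.ndarray,
    seed: int = 0,
    hidden: int = 120,
    max_iter: int = 500,
) -> StagerModel:
    """Train the 4-class stager on labelled epochs (deterministic per seed)."""
    y = np.array([STAGES4.index(l) for l in labels])
    x = features.values
    if np.unique(y).size < 2:
        raise ValueError("need at least two stage classes to train")
    net = FeedForwardNet(x.shape[1], hidden, 4, seed=seed).fit(x, y, max_iter=max_iter)
    return StagerModel(net, features.norm_params, features.names, seed)


def predict_hypnogram(model: StagerModel, features: EpochFeatureMatrix) -> Hypnogram:
    """Score epochs and merge light+deep into NREM.

    Unscorable epochs carry the label of the nearest scorable epoch and are
    flagged.  Ties break toward the earlier class in (wake, nrem, rem).
    """
    p4 = model.net.predict_proba(features.values)
    p3 = np.column_stack([p4[:, 0], p4[:, 1] + p4[:, 2], p4[:, 3]])
    idx3 = np.argmax(p3, axis=1)  # argmax breaks ties toward earlier class
    labels = [STAGES3[i] for i in idx3]
    carried = features.unscorable.copy()
    scorable = np.flatnonzero(~carried)
    if scorable.size:
        for i in np.flatnonzero(carried):
            j = scorable[np.argmin(np.abs(scorable - i))]
            labels[i] = labels[j]
    return Hypnogram(labels=labels, proba4=p4, carried=carried)


def fourfold_cv(
    features: EpochFeatureMatrix,
    labels: list[str] | np.ndarray,
    seed: int = 0,
    hidden: int = 120,
    max_iter: int = 300,
) -> list[float]:
    """Fourfold cross-validation: contiguous equal segments, per-fold
    3-class accuracy on the held-out segment."""
    y = np.array([STAGES4.index(l) for l in labels])
    n = y.size
    bounds = np.linspace(0, n, 5).astype(int)
    accs = []
    for k in range(4):
        test = np.zeros(n, dtype=bool)
        test[bounds[k] : bounds[k + 1]] = True
        xtr = features.values[~test]
        net = FeedForwardNet(xtr.shape[1], hidden, 4, seed=seed + k).fit(
            xtr, y[~test], max_iter=max_iter
        )
        p4 = net.predict_proba(features.values[test])
        p3 = np.column_stack([p4[:, 0], p4[:, 1] + p4[:, 2], p4[:, 3]])
        merged_true = np.array([0 if c == 0 else (2 if c == 3 else 1) for c in y[test]])
        accs.append(float(np.mean(np.argmax(p3, axis=1) == merged_true)))
    return accs
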