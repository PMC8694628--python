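"""Apnea/hypopnea detection and event post-processing.

A residual CNN scores 30-s element-analysis scalogram epochs (10-s stride,
i.e. 20-s overlap, so event onsets are localized to within 10 s) with a
confidence in [0, 1].  A parametric gate — a boosted decision-tree
ensemble trained with random undersampling of the majority class (RUS
boosting) on signal-quality metrics and the derived vitals (PEP, LVET, HR,
RR, SpO2) — rejects detections that coincide with systemic noise such as
position changes.  Surviving epoch detections are merged into events, the
AASM 10-s separation rule is enforced, and the apnea-hypopnea index (AHI)
is computed against total sleep time.  Apneas and hypopneas are detected
without distinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .nn import ResidualCNN, residual_layers_for_depth

__all__ = [
    "EventList",
    "build_rcnn",
    "epoch_labels",
    "train_apnea",
    "RusBoostGate",
    "parametric_gate",
    "postprocess_events",
]

GATE_FEATURES = [
    "periodicity", "repeatability", "pep", "lvet", "hr", "rr",
    "spo2_drop", "re_ratio",
]


@dataclass
class EventList:
    """Post-processed events with confidences and the AHI summary."""

    events: list[tuple[float, float, float]]  # (onset s, offset s, confidence)
    total_sleep_time: float
    min_gap: float = 10.0

    def __post_init__(self) -> None:
        onsets = [e[0] for e in self.events]
        if any(b - a < self.min_gap for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets violate the 10-s separation rule")

    @property
    def ahi(self) -> float:
        """Events per hour of sleep."""
        hours = self.total_sleep_time / 3600.0
        return len(self.events) / hours if hours > 0 else float("nan")


def build_rcnn(
    depth_blocks: int = 8, raster: int = 32, seed: int = 0, total_layers: int | None = None
) -> ResidualCNN:
    """Residual CNN spec: desk-scale default 8 blocks; pass
    ``total_layers=115`` for the deep configuration."""
    if total_layers is not None:
        depth_blocks = residual_layers_for_depth(total_layers)
    return ResidualCNN(raster=raster, n_blocks=depth_blocks, seed=seed)


def epoch_labels(
    events: list[tuple[float, float, str]] | list[tuple[float, float]],
    starts: np.ndarray,
    epoch_len: float = 30.0,
) -> np.ndarray:
    """Binary epoch labels: positive when at least 50 % of a scored event
    overlaps the epoch (events shorter than the epoch count by their own
    duration)."""
    out = np.zeros(len(starts), dtype=int)
    for ev in events:
        onset, offset = float(ev[0]), float(ev[1])
        need = 0.5 * min(offset - onset, epoch_len)
        for i, t0 in enumerate(starts):
            overlap = min(offset, t0 + epoch_len) - max(onset, t0)
            if overlap >= need > 0:
                out[i] = 1
    return out


def train_apnea(
    model: ResidualCNN,
    images: np.ndarray,
    labels: np.ndarray,
    epochs: int = 30,
    lr: float = 3e-3,
) -> ResidualCNN:
    """Train the epoch classifier (weighted loss handles class imbalance;
    deterministic for the model's construction seed)."""
    return model.fit(images, labels, epochs=epochs, lr=lr)


class RusBoostGate:
    """RUS-boosted tree ensemble over quality metrics and vitals features.

    Each boosting round undersamples the majority class to the minority
    size before fitting a shallow decision tree; rounds are combined with
    AdaBoost weights.  The gate's job is to reject epoch detections whose
    parametric signature (quality + vitals) is inconsistent with a true
    breathing event.
    """

    def __init__(self, n_rounds: int = 30, max_depth: int = 3, seed: int = 0):
        self.n_rounds = n_rounds
        self.max_depth = max_depth
        self.seed = seed
        self.trees: list[DecisionTreeClassifier] = []
        self.alphas: list[float] = []

    def fit(self, x: np.ndarray, y: np.ndarray) -> "RusBoostGate":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("gate needs both classes")
        rng = np.random.default_rng(self.seed)
        n = y.size
        w = np.full(n, 1.0 / n)
        minority = int(np.argmin(np.bincount(y)))
        idx_min = np.flatnonzero(y == minority)
        idx_maj = np.flatnonzero(y != minority)
        for t in range(self.n_rounds):
            take = rng.choice(idx_maj, size=idx_min.size, replace=False)
            idx = np.concatenate([idx_min, take])
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth, random_state=self.seed + t
            ).fit(x[idx], y[idx], sample_weight=w[idx])
            pred = tree.predict(x)
            err = float(np.sum(w[pred != y]))
            err = min(max(err, 1e-10), 1 - 1e-10)
            alpha = 0.5 * np.log((1 - err) / err)
            if alpha <= 0:
                break
            self.trees.append(tree)
            self.alphas.append(alpha)
            w *= np.exp(alpha * np.where(pred != y, 1.0, -1.0))
            w /= w.sum()
        if not self.trees:  # degenerate: single majority vote
            tree = DecisionTreeClassifier(max_depth=1, random_state=self.seed).fit(x, y)
            self.trees, self.alphas = [tree], [1.0]
        return self

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        """Weighted-vote score in [-1, 1]: positive means event-consistent."""
        x = np.asarray(x, dtype=float)
        score = np.zeros(x.shape[0])
        for tree, a in zip(self.trees, self.alphas):
            score += a * (2.0 * tree.predict(x) - 1.0)
        return score / max(sum(self.alphas), 1e-12)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.decision_function(x) > 0).astype(int)


def parametric_gate(
    confidences: np.ndarray,
    features: np.ndarray,
    quality_accept: np.ndarray | None = None,
    gate: RusBoostGate | None = None,
    labels: np.ndarray | None = None,
    seed: int = 0,
    threshold: float = 0.5,
    mode: str = "veto",
    margin: float = 0.3,
) -> tuple[np.ndarray, RusBoostGate]:
    """Combine the CNN confidence with the parametric features.

    ``mode='veto'`` (default): the ensemble sees only the parametric
    features and rejects detections whose vote score falls below
    ``-margin`` — with the default margin only confidently
    event-inconsistent epochs are vetoed, so the gate strips systemic
    noise without re-deciding borderline detections.  ``mode='fusion'``:
    the boosted-tree ensemble takes the CNN confidence *plus* the
    quality/vitals features and emits the final per-epoch confidence.
    In both modes the quality-gate mask vetoes outright.

    When `labels` are given a new gate is trained; otherwise a fitted
    `gate` must be supplied.  Returns (filtered confidences, the gate).
    """
    conf = np.asarray(confidences, dtype=float).copy()
    x = (
        np.column_stack([conf, features]) if mode == "fusion" else np.asarray(features)
    )
    if gate is None:
        if labels is None:
            raise ValueError("need labels to train a gate, or a fitted gate")
        gate = RusBoostGate(seed=seed).fit(x, labels)
    score = gate.decision_function(x)
    if mode == "fusion":
        out = np.clip(0.5 + 0.5 * score, 0.0, 1.0)
    else:
        keep = score > -margin
        out = conf.copy()
        out[(conf >= threshold) & ~keep] = 0.0
    if quality_accept is not None:
        bad = ~np.asarray(quality_accept, dtype=bool)
        out[bad & (out >= threshold)] = 0.0
    return out, gate


def enforce_min_run(
    confidences: np.ndarray,
    threshold: float = 0.5,
    support: float | None = None,
) -> np.ndarray:
    """Suppress detections without neighbor support (hysteresis).

    A scoreable event lasts at least 10 s, so on the 10-s-stride grid it
    must leave a footprint in at least two consecutive 30-s epochs.  A
    detection therefore survives only if an adjacent epoch reaches the
    `support` confidence (default: half the detection threshold); isolated
    spikes with indifferent neighbors are zeroed.
    """
    conf = np.asarray(confidences, dtype=float).copy()
    if support is None:
        support = 0.5 * threshold
    pos = conf >= threshold
    near = conf >= support
    for i in np.flatnonzero(pos):
        left = near[i - 1] if i > 0 else False
        right = near[i + 1] if i + 1 < conf.size else False
        if not (left or right):
            conf[i] = 0.0
    return conf


def postprocess_events(
    starts: np.ndarray,
    confidences: np.ndarray,
    epoch_len: float = 30.0,
    stride: float = 10.0,
    threshold: float = 0.5,
    min_gap: float = 10.0,
    total_sleep_time: float | None = None,
    refine_onsets: bool = False,
) -> EventList:
    """Merge positive epochs into events and enforce the 10-s rule.

    Consecutive positive epochs (on the stride grid) form one event from
    the first epoch's start to the last epoch's end; events separated by
    less than `min_gap` seconds are merged (simultaneous apnea/hypopnea
    collapse to a single reported event); confidence is the maximum over
    the merged members.

    ``refine_onsets`` deconvolves the epoch support: an epoch goes
    positive when at least half the event overlaps it, so the positive run
    extends roughly half an epoch beyond the event on each side; shrinking
    the run accordingly localizes the onset to the stride grid (about
    +-5 s) instead of the raw epoch span (up to ~20 s early).
    """
    starts = np.asarray(starts, dtype=float)
    conf = np.asarray(confidences, dtype=float)
    pos = conf >= threshold
    raw: list[list[float]] = []
    for i in np.flatnonzero(pos):
        t0, t1, c = starts[i], starts[i] + epoch_len, conf[i]
        if raw and t0 - raw[-1][1] <= 0:  # overlapping/adjacent epochs
            raw[-1][1] = max(raw[-1][1], t1)
            raw[-1][2] = max(raw[-1][2], c)
        else:
            raw.append([t0, t1, c])
    if refine_onsets:
        # An epoch goes positive when >= half the event overlaps it.  For
        # an event of duration d <= epoch_len the positive-epoch starts
        # span exactly epoch_len regardless of d, centred at
        # onset + d/2 - epoch_len/2; for d > epoch_len they span d,
        # starting at onset - epoch_len/2.  Inverting (with d unknown
        # within its regime) localizes onset and offset to within the
        # stride grid (~ +-(stride/2 + d-ambiguity/2) <= 10 s).
        refined: list[list[float]] = []
        for t0, t1, c in raw:
            first, last = t0, t1 - epoch_len  # first/last positive starts
            span = last - first
            if span <= epoch_len - stride / 2:  # short-event regime
                mid = 0.5 * (first + last)
                onset = mid + stride / 2
                offset = mid + epoch_len - stride / 2
            else:
                onset = first + epoch_len / 2
                offset = last + epoch_len / 2
            if offset - onset < 10.0:  # scored events last >= 10 s
                centre = 0.5 * (onset + offset)
                onset, offset = centre - 5.0, centre + 5.0
            refined.append([onset, offset, c])
        raw = refined
    merged: list[list[float]] = []
    for ev in raw:
        if merged and ev[0] - merged[-1][1] < min_gap:
            merged[-1][1] = max(merged[-1][1], ev[1])
            merged[-1][2] = max(merged[-1][2], ev[2])
        else:
            merged.append(list(ev))
    tst = total_sleep_time if total_sleep_time is not None else (
        float(starts[-1] + epoch_len) if starts.size else 0.0
    )
    return EventList(
        events=[(e[0], e[1], e[2]) for e in merged],
        total_sleep_time=tst,
        min_gap=min_gap,
    )
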