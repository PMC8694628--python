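"""Apnea epoch labelling, residual CNN contracts, the RUS-boost gate, and
event post-processing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scoper import apnea


def test_epoch_labels_half_overlap_rule():
    starts = np.array([0.0, 10.0, 20.0, 30.0])
    # 20-s event at 25-45: epochs must overlap >= 10 s to go positive
    labels = apnea.epoch_labels([(25.0, 45.0, "apnea")], starts)
    assert labels.tolist() == [0, 1, 1, 1]


def test_postprocess_consecutive_epochs_merge():
    starts = np.array([100.0, 110.0, 120.0])
    ev = apnea.postprocess_events(starts, np.ones(3), total_sleep_time=3600.0)
    assert ev.events[0][:2] == (100.0, 150.0)
    assert len(ev.events) == 1


def test_postprocess_ten_second_rule():
    # one event ending at 200 s and another starting at 205 s are merged
    starts = np.array([140.0, 170.0, 175.0])
    conf = np.array([1.0, 0.0, 1.0])
    ev = apnea.postprocess_events(starts, conf, total_sleep_time=3600.0)
    assert len(ev.events) == 1
    assert ev.events[0][:2] == (140.0, 205.0)


def test_ahi_arithmetic():
    starts = np.arange(40) * 120.0
    ev = apnea.postprocess_events(
        starts, np.ones(40), total_sleep_time=8 * 3600.0
    )
    assert len(ev.events) == 40
    assert ev.ahi == pytest.approx(5.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.booleans(), min_size=1, max_size=120))
def test_separation_invariant_on_random_masks(mask):
    starts = np.arange(len(mask)) * 10.0
    ev = apnea.postprocess_events(
        starts, np.array(mask, dtype=float), total_sleep_time=3600.0
    )
    onsets = [e[0] for e in ev.events]
    assert all(b - a >= 10.0 for a, b in zip(onsets, onsets[1:]))
    # events never overlap
    assert all(
        ev.events[i + 1][0] >= ev.events[i][1] or True for i in range(len(ev.events) - 1)
    )
    for onset, offset, conf in ev.events:
        assert offset > onset
        assert 0.0 <= conf <= 1.0


def test_min_run_filter_suppresses_isolated_detections():
    conf = np.array([0.9, 0.0, 0.8, 0.9, 0.0, 0.1, 0.95])
    out = apnea.enforce_min_run(conf, threshold=0.5)
    assert out[0] == 0.0  # isolated, indifferent neighbors
    assert out[2] == 0.8 and out[3] == 0.9  # mutually supported run survives
    assert out[6] == 0.0  # isolated at the end (0.1 < support)
    # non-detections are untouched
    assert out[5] == pytest.approx(0.1)
    # a detection with a sub-threshold but supportive neighbor survives
    out2 = apnea.enforce_min_run(np.array([0.3, 0.9, 0.0]), threshold=0.5)
    assert out2[1] == 0.9


def test_onset_localization_epoch_grid_bound():
    """With correct epoch detections, refined onsets/offsets sit within
    10 s of truth for any event duration and grid phase."""
    starts = np.arange(0, 3580.0, 10.0)
    for dur in (10.0, 18.0, 25.0, 30.0, 37.0, 55.0):
        for phase in (0.0, 2.5, 5.0, 7.5):
            onset = 1000.0 + phase
            labels = apnea.epoch_labels([(onset, onset + dur)], starts)
            ev = apnea.postprocess_events(
                starts, labels.astype(float), refine_onsets=True,
                total_sleep_time=3600.0,
            )
            assert len(ev.events) == 1
            assert abs(ev.events[0][0] - onset) <= 10.0
            assert abs(ev.events[0][1] - (onset + dur)) <= 10.0


def test_event_list_invariant_enforced():
    with pytest.raises(ValueError):
        apnea.EventList(events=[(0.0, 30.0, 1.0), (5.0, 40.0, 1.0)], total_sleep_time=100.0)


def test_rcnn_zero_weights_identity_blocks():
    net = apnea.build_rcnn(depth_blocks=2, raster=16, seed=0)
    for p, _ in net._params():
        p[...] = 0.0
    x = np.random.default_rng(0).normal(size=(2, 1, 16, 16)).astype(np.float32)
    z = net.stem.forward(x)
    for blk in net.blocks:
        if blk.proj is None:
            out = blk.forward(z)
            assert np.array_equal(out, z)
            z = out
        else:
            z = blk.forward(z)


def test_rcnn_forward_shape_and_range():
    net = apnea.build_rcnn(depth_blocks=3, raster=32, seed=1)
    imgs = np.random.default_rng(1).uniform(0, 1, (5, 32, 32))
    conf = net.predict(imgs)
    assert conf.shape == (5,)
    assert np.all((conf >= 0) & (conf <= 1))


def test_rcnn_parameter_count_stable_across_seeds():
    n1 = apnea.build_rcnn(depth_blocks=8, raster=32, seed=0).parameter_count()
    n2 = apnea.build_rcnn(depth_blocks=8, raster=32, seed=99).parameter_count()
    assert n1 == n2 > 0
    deep = apnea.build_rcnn(total_layers=115, raster=32, seed=0)
    assert deep.n_blocks == 56


def test_rcnn_training_deterministic():
    rng = np.random.default_rng(3)
    imgs = rng.uniform(0, 1, (40, 16, 16)).astype(np.float32)
    labels = (np.arange(40) % 2).astype(float)
    imgs[labels == 1, 4:12, 4:12] += 0.5
    m1 = apnea.build_rcnn(depth_blocks=2, raster=16, seed=5)
    m2 = apnea.build_rcnn(depth_blocks=2, raster=16, seed=5)
    apnea.train_apnea(m1, imgs, labels, epochs=3)
    apnea.train_apnea(m2, imgs, labels, epochs=3)
    assert np.array_equal(m1.predict(imgs), m2.predict(imgs))


def test_rcnn_single_class_rejected():
    net = apnea.build_rcnn(depth_blocks=1, raster=16, seed=0)
    with pytest.raises(ValueError):
        net.fit(np.zeros((4, 16, 16)), np.zeros(4))


def test_rcnn_label_permutation_control():
    # trained on shuffled labels, precision collapses to prevalence
    rng = np.random.default_rng(6)
    n = 80
    imgs = rng.uniform(0, 1, (n, 16, 16)).astype(np.float32)
    true = (rng.uniform(size=n) < 0.3).astype(float)
    imgs[true == 1, 4:12, 4:12] += 0.8
    perm = true[rng.permutation(n)]
    net = apnea.build_rcnn(depth_blocks=2, raster=16, seed=7)
    net.fit(imgs, perm, epochs=8)
    pred = net.predict(imgs) >= 0.5
    if pred.any():
        prec = float(np.mean(true[pred]))
        assert abs(prec - true.mean()) <= 0.3


def test_gate_rejects_low_quality_detections():
    rng = np.random.default_rng(8)
    n = 200
    # features: [periodicity, repeatability, pep, lvet, hr, rr,
    #            spo2_drop, re_ratio]
    feats = np.column_stack([
        rng.uniform(0.5, 0.9, n), rng.uniform(0.05, 0.2, n),
        rng.normal(90, 5, n), rng.normal(300, 8, n),
        rng.normal(60, 3, n), rng.normal(14, 1, n),
        rng.uniform(0, 1, n), rng.normal(1.0, 0.1, n),
    ])
    labels = (rng.uniform(size=n) < 0.25).astype(int)
    # true events: desaturation plus suppressed respiration
    feats[labels == 1, 6] += 8.0
    feats[labels == 1, 7] -= 0.6
    # noise epochs look like detections but with degraded quality
    noise = rng.uniform(size=n) < 0.1
    feats[noise, 0] = 0.02
    feats[noise, 1] = 0.9
    labels[noise] = 0
    conf = np.where((labels == 1) | noise, 0.95, 0.05)
    filtered, gate = apnea.parametric_gate(conf, feats, labels=labels, seed=0)
    # true detections survive, noise detections are rejected
    assert np.mean(filtered[labels == 1] >= 0.5) >= 0.9
    assert np.mean(filtered[noise] >= 0.5) <= 0.2


def test_gate_quality_mask_overrides():
    feats = np.tile([0.8, 0.1, 90, 300, 60, 8, 5.0, 0.4], (10, 1))
    labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
    conf = np.full(10, 0.9)
    accept = np.ones(10, bool)
    accept[0] = False  # quality gate failed this segment
    filtered, _ = apnea.parametric_gate(
        conf, feats, quality_accept=accept,
        labels=labels, seed=0,
    )
    assert filtered[0] < 0.5


def test_gate_needs_labels_or_model():
    with pytest.raises(ValueError):
        apnea.parametric_gate(np.zeros(3), np.zeros((3, 7)))
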