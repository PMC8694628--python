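"""Epoch features and the FFNN sleep stager."""

import numpy as np
import pandas as pd
import pytest

from scoper import staging
from scoper.staging import STAGES4


def _vitals(n_epochs, const=None, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n_epochs * 3) * 10.0 + 5.0
    cols = {"time": t}
    for name in ("hr", "rr", "spo2"):
        cols[name] = (
            np.full(t.size, 60.0) if const else 60.0 + rng.normal(0, 5, t.size)
        )
    return pd.DataFrame(cols)


def test_feature_matrix_shape_and_names():
    n = 12
    f = staging.build_epoch_features(_vitals(n), None, np.zeros(n), n)
    assert f.values.shape[0] == n
    assert len(f.names) == f.values.shape[1]
    assert len(set(f.names)) == len(f.names)


def test_constant_vitals_normalize_to_half_with_warning():
    n = 10
    with pytest.warns(UserWarning):
        f = staging.build_epoch_features(_vitals(n, const=True), None, None, n)
    # every constant column maps to 0.5
    assert np.allclose(f.values[:, [f.names.index("hr_mean")]], 0.5)


def test_identical_signal_segments_give_identical_rows():
    n = 6
    v = _vitals(n, const=True)
    with pytest.warns(UserWarning):
        f = staging.build_epoch_features(v, None, np.zeros(n), n)
    assert np.allclose(f.values[1], f.values[2])


def test_unscorable_epoch_flagging():
    n = 8
    v = _vitals(n)
    v.loc[(v.time >= 30) & (v.time < 120), ["hr", "rr", "spo2"]] = np.nan
    f = staging.build_epoch_features(v, None, None, n)
    assert f.unscorable[2]
    assert not f.unscorable[0]
    # imputation leaves no NaNs behind
    assert np.isfinite(f.values).all()


def _separable_features(n_per_class=40, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k in range(4):
        mu = np.zeros(12)
        mu[k * 3 : k * 3 + 3] = 3.0 * sd
        rows.append(rng.normal(mu, sd, size=(n_per_class, 12)))
        labels += [STAGES4[k]] * n_per_class
    x = np.vstack(rows)
    order = rng.permutation(x.shape[0])
    x, labels = x[order], [labels[i] for i in order]
    from scoper.preprocess import min_max_normalize

    xn, params = min_max_normalize(x)
    f = staging.EpochFeatureMatrix(
        values=xn, names=[f"f{i}" for i in range(12)], norm_params=params,
        unscorable=np.zeros(x.shape[0], bool), raw=x,
    )
    return f, labels


def test_separable_classes_learned():
    f, labels = _separable_features()
    n = len(labels)
    tr = slice(0, int(0.75 * n))
    te = slice(int(0.75 * n), n)
    ftr = staging.EpochFeatureMatrix(
        values=f.values[tr], names=f.names, norm_params=f.norm_params,
        unscorable=f.unscorable[tr], raw=f.raw[tr],
    )
    model = staging.train_stager(ftr, labels[tr], seed=0, max_iter=300)
    p4 = model.net.predict_proba(f.values[te])
    acc = np.mean([STAGES4[i] == l for i, l in zip(np.argmax(p4, 1), labels[te])])
    assert acc >= 0.95


def test_label_permutation_control_near_chance():
    f, labels = _separable_features(seed=1)
    rng = np.random.default_rng(2)
    perm = [labels[i] for i in rng.permutation(len(labels))]
    n = len(labels)
    tr, te = slice(0, int(0.75 * n)), slice(int(0.75 * n), n)
    ftr = staging.EpochFeatureMatrix(
        values=f.values[tr], names=f.names, norm_params=f.norm_params,
        unscorable=f.unscorable[tr], raw=f.raw[tr],
    )
    model = staging.train_stager(ftr, perm[tr], seed=0, max_iter=200)
    p4 = model.net.predict_proba(f.values[te])
    acc = np.mean([STAGES4[i] == l for i, l in zip(np.argmax(p4, 1), perm[te])])
    assert acc <= 0.35  # chance for 4 balanced classes


def test_training_is_deterministic():
    f, labels = _separable_features()
    m1 = staging.train_stager(f, labels, seed=3, max_iter=50)
    m2 = staging.train_stager(f, labels, seed=3, max_iter=50)
    assert np.array_equal(m1.net.w1, m2.net.w1)
    assert np.array_equal(m1.net.w2, m2.net.w2)


def test_single_class_labels_rejected():
    f, labels = _separable_features()
    with pytest.raises(ValueError):
        staging.train_stager(f, ["wake"] * len(labels), seed=0)


def test_merge_rule_and_simplex():
    f, labels = _separable_features()
    model = staging.train_stager(f, labels, seed=0, max_iter=100)
    hyp = staging.predict_hypnogram(model, f)
    assert np.allclose(hyp.proba4.sum(axis=1), 1.0, atol=1e-9)
    # merging pools light+deep and leaves wake/rem untouched
    assert np.allclose(hyp.proba3[:, 0], hyp.proba4[:, 0])
    assert np.allclose(hyp.proba3[:, 2], hyp.proba4[:, 3])
    assert np.allclose(hyp.proba3[:, 1], hyp.proba4[:, 1] + hyp.proba4[:, 2])


def test_merge_probabilities_example():
    p4 = np.array([[0.1, 0.3, 0.4, 0.2]])
    hyp = staging.Hypnogram(labels=["nrem"], proba4=p4)
    assert hyp.proba3[0, 1] == pytest.approx(0.7)


def test_tie_breaks_to_earlier_class():
    class Net:
        def predict_proba(self, x):
            return np.tile([0.5, 0.0, 0.0, 0.5], (x.shape[0], 1))

    model = staging.StagerModel(Net(), (np.zeros(1), np.ones(1)), ["f0"], 0)
    f = staging.EpochFeatureMatrix(
        values=np.zeros((3, 1)), names=["f0"],
        norm_params=(np.zeros(1), np.ones(1)), unscorable=np.zeros(3, bool),
    )
    hyp = staging.predict_hypnogram(model, f)
    assert hyp.labels == ["wake"] * 3


def test_unscorable_carries_nearest_label():
    class Net:
        def predict_proba(self, x):
            p = np.tile([0.7, 0.1, 0.1, 0.1], (x.shape[0], 1))
            p[-1] = [0.0, 0.0, 0.0, 1.0]
            return p

    model = staging.StagerModel(Net(), (np.zeros(1), np.ones(1)), ["f0"], 0)
    f = staging.EpochFeatureMatrix(
        values=np.zeros((4, 1)), names=["f0"],
        norm_params=(np.zeros(1), np.ones(1)),
        unscorable=np.array([False, False, False, True]),
    )
    hyp = staging.predict_hypnogram(model, f)
    assert hyp.labels[-1] == "wake"  # carried from nearest scorable epoch
    assert hyp.carried[-1]


def test_fourfold_cv_runs():
    f, labels = _separable_features(n_per_class=20)
    accs = staging.fourfold_cv(f, labels, seed=0, max_iter=60)
    assert len(accs) == 4
    assert all(0.0 <= a <= 1.0 for a in accs)
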