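"""Shrinkage-LDA and cross-validation tests."""

import numpy as np
import pytest
from scipy.stats import norm

from deltareach.decoding import (
    ShrinkageLda,
    crossval_accuracy_curve,
    loto_accuracy,
    loto_predictions,
    shuffle_significance_level,
    summarize_peaks,
)


# ------------------------------------------------------------------- sLDA


def test_accuracy_near_bayes_rate():
    """Two spherical Gaussian classes with separation delta: the optimal
    test accuracy is Phi(delta/2); a well-trained sLDA gets within 2%."""
    rng = np.random.default_rng(0)
    d, delta, n = 5, 1.5, 3000
    mean = np.zeros(d)
    mean[0] = delta / 2
    xtr = np.vstack([rng.normal(size=(n, d)) + mean, rng.normal(size=(n, d)) - mean])
    ytr = np.repeat([0, 1], n)
    xte = np.vstack([rng.normal(size=(n, d)) + mean, rng.normal(size=(n, d)) - mean])
    clf = ShrinkageLda().fit(xtr, ytr)
    acc = np.mean(clf.predict(xte) == ytr)
    assert acc == pytest.approx(norm.cdf(delta / 2), abs=0.02)


def test_full_shrinkage_equals_nearest_class_mean():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(60, 8))
    y = rng.integers(0, 3, 60)
    clf = ShrinkageLda(shrinkage=1.0).fit(x, y)
    preds = clf.predict(x)
    means = np.stack([x[y == c].mean(axis=0) for c in clf.classes_])
    nearest = clf.classes_[
        np.argmin(((x[:, None, :] - means[None]) ** 2).sum(-1), axis=1)
    ]
    assert np.array_equal(preds, nearest)


def test_singular_features_still_fit():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(30, 4))
    x = np.hstack([x, x])  # duplicated dimensions: singular sample covariance
    y = np.repeat([0, 1], 15)
    clf = ShrinkageLda().fit(x, y)
    assert np.all(np.isfinite(clf.coef_))
    assert clf.gamma_ > 0


def test_class_size_validation():
    with pytest.raises(ValueError):
        ShrinkageLda().fit(np.zeros((3, 2)), np.array([0, 1, 1]))
    with pytest.raises(ValueError):
        ShrinkageLda().fit(np.zeros((4, 2)), np.array([0, 0, 0, 0]))


def test_sklearn_api_contract():
    clf = ShrinkageLda(shrinkage=0.5)
    assert clf.get_params() == {"shrinkage": 0.5, "priors": "uniform"}
    clf.set_params(shrinkage=None)
    rng = np.random.default_rng(3)
    x = rng.normal(size=(40, 3))
    y = np.repeat([0, 1], 20)
    assert 0.0 <= clf.fit(x, y).score(x, y) <= 1.0


def test_agrees_with_sklearn_lda_direction():
    """Cross-check: with the same fixed shrinkage, the discriminant
    direction matches sklearn's LDA (lsqr, shrinkage) up to scale."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(4)
    x = np.vstack([rng.normal(size=(50, 6)) + 0.8, rng.normal(size=(50, 6))])
    y = np.repeat([1, 0], 50)
    ours = ShrinkageLda(shrinkage=0.3).fit(x, y)
    ref = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.3).fit(x, y)
    w_ours = ours.coef_[1] - ours.coef_[0]
    w_ref = ref.coef_[0]
    cos = w_ours @ w_ref / (np.linalg.norm(w_ours) * np.linalg.norm(w_ref))
    assert cos > 0.99


# --------------------------------------------------------------------- CV


def test_windowed_feature_dimension():
    rng = np.random.default_rng(5)
    data = rng.normal(size=(14, 64, 10))
    labels = np.repeat([0, 1], 7)
    curve = crossval_accuracy_curve(data, labels, mode="windowed", window_len=6)
    assert np.all(np.isnan(curve.accuracy[:5]))
    assert np.all(np.isfinite(curve.accuracy[5:]))
    # 64 channels x 6 time-points = 384 features
    from deltareach.decoding import _features_at

    assert _features_at(data, 9, "windowed", 6).shape == (14, 384)


def test_separable_features_perfect_accuracy():
    rng = np.random.default_rng(6)
    data = rng.normal(size=(20, 4, 6), scale=0.05)
    labels = np.repeat([0, 1], 10)
    data[labels == 1, :, 3] += 5.0
    curve = crossval_accuracy_curve(data, labels)
    assert curve.accuracy[3] == 1.0


def test_loto_matches_fold_enumeration():
    """12-trial toy problem: the curve equals an explicit enumeration of
    all 12 train/test splits."""
    rng = np.random.default_rng(7)
    data = rng.normal(size=(12, 3, 4))
    labels = np.array([0, 1] * 6)
    curve = crossval_accuracy_curve(data, labels)
    for t in range(4):
        preds = []
        for i in range(12):
            train = np.setdiff1d(np.arange(12), [i])
            clf = ShrinkageLda().fit(data[train, :, t], labels[train])
            preds.append(clf.predict(data[i : i + 1, :, t])[0])
        assert np.array_equal(curve.predictions[:, t], preds)
        assert curve.accuracy[t] == pytest.approx(np.mean(preds == labels))


def test_each_trial_tested_once():
    rng = np.random.default_rng(8)
    x = rng.normal(size=(16, 3))
    y = np.repeat([0, 1], 8)
    preds = loto_predictions(x, y)
    assert preds.shape == (16,)


def test_minimum_trial_count():
    with pytest.raises(ValueError):
        crossval_accuracy_curve(np.zeros((8, 2, 3)), np.repeat([0, 1], 4))


# ---------------------------------------------------------------- shuffles


def test_shuffle_mean_near_chance():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(60, 8))
    y = np.repeat([0, 1], 30)
    thr, accs = shuffle_significance_level(
        x, y, n_shuffles=150, seed=0, return_accuracies=True
    )
    assert abs(accs.mean() - 0.5) < 0.05
    assert thr >= np.median(accs)  # 95th >= 50th percentile


def test_shuffle_determinism_matches_manual_recomputation():
    rng = np.random.default_rng(10)
    x = rng.normal(size=(20, 4))
    y = np.repeat([0, 1], 10)
    thr = shuffle_significance_level(x, y, n_shuffles=100, seed=3)
    manual_rng = np.random.default_rng(3)
    accs = []
    for _ in range(100):
        perm = manual_rng.permutation(20)
        accs.append(loto_accuracy(x, y[perm]))
    assert thr == pytest.approx(np.percentile(accs, 95.0))


def test_shuffle_count_validation():
    with pytest.raises(ValueError):
        shuffle_significance_level(np.zeros((20, 2)), np.repeat([0, 1], 10), n_shuffles=50)


def test_null_exceedance_rate_near_alpha():
    """Null features: the fraction of time-points whose accuracy exceeds
    the 95th-percentile shuffle threshold stays near 5%."""
    rng = np.random.default_rng(11)
    data = rng.normal(size=(40, 6, 80))
    y = np.repeat([0, 1], 20)
    curve = crossval_accuracy_curve(data, y)
    thr = shuffle_significance_level(data[:, :, 0], y, n_shuffles=150, seed=1)
    rate = np.mean(curve.accuracy[1:] > thr)
    assert rate <= 0.15


def test_permuting_trial_order_keeps_accuracy():
    rng = np.random.default_rng(12)
    data = rng.normal(size=(16, 3, 5))
    labels = np.array([0, 1] * 8)
    perm = rng.permutation(16)
    a = crossval_accuracy_curve(data, labels)
    b = crossval_accuracy_curve(data[perm], labels[perm])
    assert np.allclose(a.accuracy, b.accuracy)


# ------------------------------------------------------------------- peaks


def test_confusion_matrix_structure():
    rng = np.random.default_rng(13)
    data = rng.normal(size=(24, 4, 5), scale=0.01)
    labels = np.repeat(["a", "b", "c"], 8)
    for i, lab in enumerate(["a", "b", "c"]):
        data[labels == lab, :, 2] += 10.0 * (i + 1)
    curve = crossval_accuracy_curve(data, labels)
    cm = curve.confusion_at(curve.times[2])
    assert np.array_equal(cm, np.diag([8, 8, 8]))  # perfect classifier
    cm_any = curve.confusion_at(curve.times[0])
    assert np.array_equal(cm_any.sum(axis=1), [8, 8, 8])  # row conservation


def test_peak_summary_and_paired_differences():
    rng = np.random.default_rng(14)
    curves = {}
    for s in range(3):
        for al, boost in (("trial_start", 0.6), ("movement_onset", 0.1)):
            data = rng.normal(size=(20, 3, 8), scale=1.0)
            y = np.repeat([0, 1], 10)
            data[y == 1, :, 4] += boost + 0.2 * s
            curves[(s, al)] = crossval_accuracy_curve(
                data, y, alignment=al, times=np.arange(8) / 10.0
            )
    summary = summarize_peaks(
        curves,
        {"trial_start": (0.0, 0.8), "movement_onset": (0.0, 0.8)},
    )
    assert len(summary.peaks) == 6
    assert summary.paired_differences is not None
    assert len(summary.paired_differences) == 3


def test_monotone_response_to_direction_amplitude():
    """Increasing the simulated direction-signal amplitude never decreases
    the mean peak decoding accuracy (paired seeds, 3-point grid)."""
    from deltareach.epochs import extract_epochs
    from deltareach.preprocess import filter_signal, resample_signal
    from deltareach.simulate import SimulationConfig, generate_experiment

    amps = (0.05, 0.5, 2.0)
    mean_peaks = []
    for amp in amps:
        peaks = []
        for seed in (1, 2):
            cfg = SimulationConfig(n_trials=24, n_voxels=96, dir_amp=amp)
            exp = generate_experiment(cfg, seed=seed)
            delta = resample_signal(
                filter_signal(exp.eeg, "lowpass", 3.0), 10.0
            )
            ep = extract_epochs(
                delta, exp.trials["t_trial_start"].to_numpy(), (2.45, 3.35)
            )
            curve = crossval_accuracy_curve(
                ep, exp.trials["direction"].to_numpy()
            )
            peaks.append(np.nanmax(curve.accuracy))
        mean_peaks.append(np.mean(peaks))
    assert mean_peaks[0] <= mean_peaks[1] + 1e-9 <= mean_peaks[2] + 2e-9
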