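"""Behavioral detection and statistics tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from deltareach.behavior import (
    ROBUST_SCALE,
    OnsetDetectionParams,
    detect_all_trials,
    detect_cursor_events,
    detect_eye_onset,
    flag_outlier_trials,
    posthoc_direction_ttests,
    rm_anova_two_way,
    robust_zscore,
)
from deltareach.simulate import (
    SimulationConfig,
    generate_experiment,
    simulate_cursor_trajectory,
)


# ---------------------------------------------------------- onset detector


def _ramp(t0, slope, fs=60.0, length=6.0):
    t = np.arange(int(length * fs)) / fs
    return np.clip((t - t0) * slope, 0.0, None)


def test_ramp_onset_exact():
    """The tangent of a line passes through its own zero: for a ramp whose
    threshold crossing lies beyond the smoothing transition band, the
    detected onset equals the true onset to within one sample."""
    fs = 60.0
    for t0 in (2.9, 3.1, 3.4):
        ev = detect_cursor_events(_ramp(t0, 0.3, fs), fs)
        assert abs(ev.onset - t0) <= 1.0 / fs + 1e-9


def test_ramp_baseline_invariance():
    fs = 60.0
    a = detect_cursor_events(_ramp(3.1, 0.3, fs), fs)
    b = detect_cursor_events(_ramp(3.1, 0.3, fs) + 0.27, fs)
    assert a.onset == pytest.approx(b.onset, abs=1e-12)


def test_min_jerk_onset_within_50ms():
    fs = 60.0
    for onset, dur in [(3.0, 0.45), (3.23, 0.49), (3.5, 0.55)]:
        tr = simulate_cursor_trajectory("right", onset, dur, fs, 0.0, length=6.0)
        ev = detect_cursor_events(tr, fs)
        assert abs(ev.onset - onset) < 0.05


def test_translation_equivariance():
    fs = 60.0
    tr = simulate_cursor_trajectory("up", 3.1, 0.5, fs, 0.0, length=6.5)
    shift = 12  # samples
    params = OnsetDetectionParams()
    a = detect_cursor_events(tr, fs, params)
    shifted = np.concatenate([np.zeros(shift), tr])[: tr.size + shift]
    params2 = OnsetDetectionParams(prep_end=params.prep_end + shift / fs)
    b = detect_cursor_events(shifted, fs, params2)
    assert b.onset - a.onset == pytest.approx(shift / fs, abs=1e-9)


def test_amplitude_scale_invariance_above_threshold():
    fs = 60.0
    tr = simulate_cursor_trajectory("up", 3.1, 0.5, fs, 0.0, length=6.0)
    a = detect_cursor_events(tr, fs)
    b = detect_cursor_events(1.8 * tr, fs)
    assert abs(a.onset - b.onset) < 0.05


def test_no_movement_flag():
    fs = 60.0
    ev = detect_cursor_events(np.zeros(int(6 * fs)) + 0.01, fs)
    assert not ev.moved and np.isnan(ev.onset)


def test_offset_and_duration():
    fs = 60.0
    tr = simulate_cursor_trajectory("down", 3.0, 0.5, fs, 0.0, length=6.0)
    ev = detect_cursor_events(tr, fs)
    # offset = first crossing of distance-to-target < 0.1, i.e. trace > 0.9
    t = np.arange(tr.size) / fs
    expected_offset = t[np.flatnonzero(tr > 0.9)[0]]
    assert ev.offset == pytest.approx(expected_offset, abs=1.5 / fs)
    assert ev.duration == pytest.approx(ev.offset - ev.onset)


def test_mean_onset_error_on_default_experiment():
    """On the default synthetic experiment the detector is accurate to
    better than 2 samples of the 60 Hz cursor trace on average."""
    cfg = SimulationConfig(n_trials=48, n_voxels=96)
    exp = generate_experiment(cfg, seed=12)
    detected = detect_all_trials(exp.cursor, exp.trials)
    err = (detected["detected_onset"] - detected["truth_move_onset"]).abs()
    assert err.notna().all()
    assert err.mean() < 2.0 / 60.0


# --------------------------------------------------------------- outliers


def test_outliers_identical_values_none():
    mask = flag_outlier_trials(np.full(10, 3.2), np.full(10, 0.5))
    assert not mask.any()


def test_outlier_far_onset_flagged():
    onsets = np.full(20, 3.2)
    onsets[3] += 10 * 0.2
    onsets += np.linspace(-0.1, 0.1, 20)  # nonzero MAD
    mask = flag_outlier_trials(onsets, np.full(20, 0.5) + np.linspace(0, 0.05, 20))
    assert mask[3]
    assert mask.sum() == 1


def test_outlier_rate_matches_normal_tail():
    """With k = 2.5 the flagged fraction of standard-normal draws matches
    the analytic two-sided tail 2*Phi(-2.5) = 1.24%."""
    rng = np.random.default_rng(42)
    x = rng.standard_normal(100_000)
    mask = robust_zscore(x) > 2.5
    expected = 2 * stats.norm.cdf(-2.5)
    assert mask.mean() == pytest.approx(expected, abs=0.001)


def test_mad_zero_edge_rule():
    x = np.array([1.0, 1.0, 1.0, 1.0, 5.0])
    z = robust_zscore(x)
    assert np.isinf(z[-1]) and np.all(z[:-1] == 0)


def test_outliers_need_three_trials():
    with pytest.raises(ValueError):
        flag_outlier_trials(np.ones(2), np.ones(2))


def test_robust_scale_constant():
    assert ROBUST_SCALE == pytest.approx(1.4826, abs=5e-5)


# --------------------------------------------------------------- eye onset


def test_eye_onset_near_catch_up_saccade():
    """With the configured 190 ms catch-up latency the detected eye
    movement onset sits near 2.69 s of trial time."""
    cfg = SimulationConfig(n_trials=32, n_voxels=96, blink_rate=0.0)
    exp = generate_experiment(cfg, seed=21)
    onsets = detect_eye_onset(exp.eeg, exp.trials)
    for d in ("right", "left"):
        assert onsets[d] is not None
        assert onsets[d] == pytest.approx(2.69, abs=0.08)


def test_eye_onset_flat_eog_none(experiment16):
    rec = experiment16.eeg.copy()
    rec.data[rec.picks("eog")] = 0.0
    onsets = detect_eye_onset(rec, experiment16.trials)
    assert all(v is None for v in onsets.values())


def test_eye_onset_step_detected_exactly():
    rec = SimulationConfig(n_trials=8, n_voxels=96)
    exp = generate_experiment(rec, seed=3)
    clean = exp.eeg.copy()
    clean.data[:] = 0.0
    heog_r = clean.channel_names.index("EOG-canthus-R")
    step_at = 2.8
    for t0 in exp.trials["t_trial_start"]:
        i = int((t0 + step_at) * clean.fs)
        clean.data[heog_r, i:] = 10.0
    onsets = detect_eye_onset(clean, exp.trials)
    assert onsets["right"] == pytest.approx(step_at, abs=1.0 / clean.fs + 1e-9)


# ------------------------------------------------------------------ ANOVA


def _manual_rm_anova(y):
    """Hand-computed sums of squares for the two-way within-subject ANOVA
    (independent oracle)."""
    s, a, b = y.shape
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)
    m_ab = y.mean(axis=0)
    out = {}
    ss_a = s * 0 + b * s * np.sum((m_a - grand) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2)
    out["condition"] = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (s - 1)))
    ss_b = a * s * np.sum((m_b - grand) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2)
    out["direction"] = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (s - 1)))
    ss_ab = s * np.sum(
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2
    )
    resid = (
        y
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - grand
    )
    ss_err = np.sum(resid**2)
    out["condition:direction"] = (ss_ab / ((a - 1) * (b - 1))) / (
        ss_err / ((a - 1) * (b - 1) * (s - 1))
    )
    return out


def test_rm_anova_matches_manual_sums_of_squares():
    rng = np.random.default_rng(5)
    y = rng.normal(size=(2, 2, 4))
    tab = rm_anova_two_way(y)
    oracle = _manual_rm_anova(y)
    for effect, f in oracle.items():
        assert tab.loc[effect, "F"] == pytest.approx(f, rel=1e-8), effect


def test_rm_anova_power_with_large_condition_shift():
    rng = np.random.default_rng(0)
    y = rng.normal(size=(10, 2, 4), scale=0.1)
    y[:, 0, :] += 5.0
    tab = rm_anova_two_way(y)
    assert tab.loc["condition", "p"] < 0.001


def test_rm_anova_type_I_error_near_alpha():
    """Pure subject noise: rejection rate of the condition effect at
    alpha = 0.05 stays near the nominal level."""
    rng = np.random.default_rng(7)
    rejections = 0
    n_rep = 150
    for _ in range(n_rep):
        y = rng.normal(size=(8, 2, 4)) + rng.normal(size=(8, 1, 1))
        tab = rm_anova_two_way(y)
        rejections += tab.loc["condition", "p"] < 0.05
    assert 0.01 <= rejections / n_rep <= 0.10


def test_rm_anova_rejects_missing_cells():
    y = np.random.default_rng(0).normal(size=(4, 2, 4))
    y[1, 0, 2] = np.nan
    with pytest.raises(ValueError):
        rm_anova_two_way(y)


def test_posthoc_bonferroni_structure():
    rng = np.random.default_rng(3)
    y = rng.normal(size=(8, 2, 4))
    tab = posthoc_direction_ttests(y)
    assert len(tab) == 6
    assert np.all(tab["p_bonferroni"] >= tab["p"] - 1e-12)
    assert np.all(tab["p_bonferroni"] <= 1.0)
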