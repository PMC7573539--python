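"""Preprocessing-chain tests against analytic and synthetic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deltareach.core import Recording
from deltareach.preprocess import (
    PreprocessConfig,
    apply_car,
    correct_eye_artifacts,
    electrode_adjacency,
    filter_signal,
    fit_eye_model,
    hear_correct,
    interpolate_channels,
    preprocess_recording,
    resample_signal,
)
from deltareach.simulate import SimulationConfig, generate_experiment


def _rec(data, fs=200.0, types=None, pos=None):
    n = data.shape[0]
    return Recording(
        data=data,
        fs=fs,
        channel_names=[f"E{i}" for i in range(n)],
        channel_types=types or ["eeg"] * n,
        channel_positions=pos,
    )


# ------------------------------------------------------------------ filters


def test_highpass_removes_dc():
    rec = _rec(np.full((2, 4000), 7.5))
    out = filter_signal(rec, "highpass", 0.4)
    assert np.abs(out.data).max() < 7.5 * 1e-6


def test_zero_phase_keeps_pulse_latency():
    x = np.zeros((1, 2000))
    x[0, 1000] = 1.0
    out = filter_signal(_rec(x), "lowpass", 3.0)
    assert np.argmax(out.data[0]) == 1000


def test_lowpass_attenuation_matches_butterworth_magnitude():
    """Two-pass 4th-order Butterworth: amplitude ratio = |H(f)|^2 with
    |H|^2 = 1 / (1 + (w/wc)^8) evaluated at the bilinear-prewarped digital
    frequencies, checked on a unit 10 Hz sinusoid for fc = 3 Hz."""
    fs, f0, fc = 200.0, 10.0, 3.0
    t = np.arange(int(40 * fs)) / fs
    rec = _rec(np.sin(2 * np.pi * f0 * t)[None, :], fs=fs)
    out = filter_signal(rec, "lowpass", fc, order=4)
    mid = out.data[0, 2000:-2000]
    measured = np.sqrt(2 * np.mean(mid**2))
    warped_ratio = np.tan(np.pi * f0 / fs) / np.tan(np.pi * fc / fs)
    expected = 1.0 / (1.0 + warped_ratio**8)
    assert measured == pytest.approx(expected, rel=0.02)
    # the analog closed form agrees up to the small warping correction
    assert expected == pytest.approx(1.0 / (1.0 + (f0 / fc) ** 8), rel=0.1)


def test_cutoff_above_nyquist_rejected():
    rec = _rec(np.zeros((1, 100)), fs=100.0)
    with pytest.raises(ValueError):
        filter_signal(rec, "lowpass", 50.0)


# ------------------------------------------------------------ interpolation


def _cap_positions(n, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.uniform(0.2, 1.0, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z]) * 0.095


def test_interpolation_identity_and_constant():
    pos = _cap_positions(16)
    data = np.full((16, 50), 3.3)
    rec = _rec(data.copy(), pos=pos)
    assert np.array_equal(interpolate_channels(rec, []).data, data)
    rec.data[4] = -99.0
    out = interpolate_channels(rec, ["E4"], pos)
    assert np.allclose(out.data[4], 3.3, atol=1e-6)
    untouched = [i for i in range(16) if i != 4]
    assert np.array_equal(out.data[untouched], data[untouched])


def test_interpolation_recovers_smooth_harmonic_field():
    """A degree-1 spherical-harmonic field is smooth; the spline estimate
    of a removed channel should land within 5% RMS of the truth."""
    pos = _cap_positions(32, seed=1)
    u = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    t = np.linspace(0, 1, 80)
    field = np.outer(1.5 * u[:, 0] + 0.8 * u[:, 2], np.sin(2 * np.pi * t) + 2)
    rec = _rec(field.copy(), pos=pos)
    rec.data[10] = 0.0
    out = interpolate_channels(rec, ["E10"], pos)
    err = np.sqrt(np.mean((out.data[10] - field[10]) ** 2))
    assert err < 0.05 * np.sqrt(np.mean(field[10] ** 2))


def test_interpolation_validates_channels():
    pos = _cap_positions(8)
    rec = _rec(np.zeros((8, 10)), pos=pos)
    with pytest.raises(ValueError):
        interpolate_channels(rec, ["nope"], pos)


# ------------------------------------------------------------------- eye


def test_eye_correction_recovers_clean_eeg():
    """Contamination is exactly linear in the artifact sources, so the
    regression/subspace model removes it almost entirely (low-noise
    recording with a long calibration block, so the fitted coefficients
    are essentially exact)."""
    cfg = SimulationConfig(
        n_trials=16,
        n_voxels=96,
        eog_noise_rms=0.0,
        noise_rms=0.05,
        sensor_noise_rms=0.01,
        calib_duration=360.0,
        calib_rest_end=120.0,
        calib_blink_end=240.0,
    )
    exp = generate_experiment(cfg, seed=2, return_components=True)
    corrected, model = correct_eye_artifacts(exp.eeg, exp.calibration)
    clean_plus_noise = exp.components["clean"] + exp.components["noise"]
    resid = corrected.data[exp.eeg.picks("eeg")] - clean_plus_noise
    assert np.sqrt(np.mean(resid**2)) < 0.02 * np.sqrt(
        np.mean(clean_plus_noise**2)
    )
    # EOG channels are untouched
    assert np.array_equal(
        corrected.data[exp.eeg.picks("eog")],
        exp.eeg.data[exp.eeg.picks("eog")],
    )


def test_eye_correction_noop_without_contamination():
    """Without contamination the fitted coefficients reflect only chance
    correlation between EEG noise and the regressors; with a long
    calibration they are small and the output stays close to the input."""
    cfg = SimulationConfig(
        n_trials=8,
        n_voxels=96,
        artifact_gain=0.0,
        calib_duration=360.0,
        calib_rest_end=120.0,
        calib_blink_end=240.0,
    )
    exp = generate_experiment(cfg, seed=4)
    corrected, model = correct_eye_artifacts(exp.eeg, exp.calibration)
    assert np.abs(model.coef).max() < 0.1
    rms = np.sqrt(np.mean(exp.eeg.data[exp.eeg.picks("eeg")] ** 2))
    delta = corrected.data - exp.eeg.data
    assert np.sqrt(np.mean(delta**2)) < 0.08 * rms


def test_eye_model_requires_calibration_duration():
    cfg = SimulationConfig(n_trials=8, n_voxels=96)
    exp = generate_experiment(cfg, seed=4)
    with pytest.raises(ValueError):
        fit_eye_model(exp.calibration, min_duration=1e4)


# ------------------------------------------------------------------- CAR


def test_car_antisymmetric_pair_unchanged():
    x = np.vstack([np.sin(np.linspace(0, 5, 100)), -np.sin(np.linspace(0, 5, 100))])
    out = apply_car(_rec(x.copy()))
    assert np.allclose(out.data, x, atol=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10**6))
def test_car_zero_mean_and_idempotent(seed):
    x = np.random.default_rng(seed).normal(size=(6, 40))
    once = apply_car(_rec(x))
    assert np.allclose(once.data.mean(axis=0), 0.0, atol=1e-12)
    twice = apply_car(once)
    assert np.allclose(twice.data, once.data, atol=1e-12)


# ------------------------------------------------------------------ HEAR


def _hear_setup(n=5, t=400, fs=200.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, t))
    pos = _cap_positions(n, seed=3)
    adjacency = electrode_adjacency(pos)
    calib_var = x.var(axis=1)
    return _rec(x, fs=fs, pos=pos), calib_var, adjacency


def test_hear_identity_below_threshold():
    rec, calib_var, adj = _hear_setup()
    out = hear_correct(rec, calib_var * 10.0, adj)  # ratio << 1 everywhere
    assert np.array_equal(out.data, rec.data)


def test_hear_saturates_on_electrode_pop():
    rec, calib_var, adj = _hear_setup()
    rec.data[2, 100:160] += 40.0  # >> 5x calibration variance
    out = hear_correct(rec, calib_var, adj, window=0.25, r_saturate=5.0)
    nb_mean = rec.data[adj[2]].mean(axis=0)
    assert np.allclose(out.data[2, 120:140], nb_mean[120:140], atol=1e-9)


def test_hear_linear_ramp_midpoint_at_ratio_three():
    """Variance ratio 3 with saturation 5 gives artifact probability 0.5:
    the output is exactly the midpoint of channel and neighbor mean."""
    n, t, fs = 4, 800, 200.0
    rng = np.random.default_rng(1)
    x = rng.standard_normal((n, t))
    pos = _cap_positions(n, seed=5)
    adj = electrode_adjacency(pos)
    calib_var = np.apply_along_axis(
        lambda v: np.convolve(v, np.ones(50) / 50, mode="same"), 1, x**2
    )
    # choose calibration variance = sliding variance / 3 -> ratio exactly 3
    out = hear_correct(
        _rec(x, fs=fs, pos=pos), np.ones(n), adj, r_saturate=5.0
    )
    ratio = calib_var  # ratio per sample when calib_var = 1
    p = np.clip((ratio - 1) / 4.0, 0, 1)
    nb = np.vstack([x[a].mean(axis=0) for a in adj])
    assert np.allclose(out.data, (1 - p) * x + p * nb, atol=1e-9)


# --------------------------------------------------------------- resample


def test_resample_counts_and_constant():
    rec = _rec(np.full((2, 4000), 2.5), fs=200.0)
    out = resample_signal(rec, 10.0)
    assert out.data.shape == (2, 200)  # 20 s at 10 Hz
    assert np.allclose(out.data, 2.5, atol=1e-9)
    with pytest.raises(ValueError):
        resample_signal(rec, 400.0)


def test_resample_preserves_slow_sinusoid():
    fs = 200.0
    t = np.arange(int(30 * fs)) / fs
    rec = _rec(np.sin(2 * np.pi * 1.0 * t)[None, :], fs=fs)
    out = resample_signal(rec, 10.0)
    t_new = np.arange(out.data.shape[1]) / 10.0
    mid = slice(30, -30)
    assert np.allclose(
        out.data[0, mid], np.sin(2 * np.pi * 1.0 * t_new)[mid], atol=0.01
    )


# ------------------------------------------------------------------ chain


def test_chain_preserves_delta_band_signal():
    """End-to-end: the artifact stages (eye correction, HEAR, notch,
    interpolation) must not corrupt the artifact-free delta-band content.
    Ground truth = the contamination-free recording (clean projection +
    brain noise) run through the same filters + CAR + decimation."""
    cfg = SimulationConfig(n_trials=24, n_voxels=96)
    exp = generate_experiment(cfg, seed=9, return_components=True)
    res = preprocess_recording(exp.eeg, exp.calibration, PreprocessConfig())

    truth = exp.components["clean"] + exp.components["noise"]
    ref = Recording(
        data=truth.copy(),
        fs=exp.eeg.fs,
        channel_names=[f"E{i}" for i in range(truth.shape[0])],
        channel_types=["eeg"] * truth.shape[0],
    )
    ref = filter_signal(ref, "highpass", 0.4)
    ref = apply_car(ref)
    ref = filter_signal(ref, "lowpass", 3.0)
    ref = resample_signal(ref, 10.0)

    out = res.delta.data[res.delta.picks("eeg")]
    corr = [
        np.corrcoef(out[i], ref.data[i])[0, 1] for i in range(out.shape[0])
    ]
    assert np.mean(corr) > 0.95


def test_eye_correction_removes_frontal_direction_effect():
    """Gaze follows the cued direction, so uncorrected EEG carries strong
    direction-related activity at the channels closest to the eyes; after
    correction the frontal direction-encoding effect (GLM direction-factor
    norm around the saccade, above its pre-cue baseline) drops by > 10x."""
    from deltareach.encoding import build_design_matrix, fit_glm_epochs
    from deltareach.epochs import extract_epochs

    cfg = SimulationConfig(n_trials=64, n_voxels=96, eog_noise_rms=0.0)
    exp = generate_experiment(cfg, seed=6)
    u = exp.leadfield.channel_positions
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    frontal = np.flatnonzero(u[:, 1] > 0.75)
    design = build_design_matrix(exp.trials, seed=0)

    def frontal_dir_effect(task_rec):
        delta = resample_signal(filter_signal(task_rec, "lowpass", 3.0), 10.0)
        ep = extract_epochs(
            delta, exp.trials["t_trial_start"].to_numpy(), (0.75, 4.75)
        )
        a = fit_glm_epochs(ep.subset(design.trial_index), design)
        dirnorm = np.linalg.norm(a[:, frontal][:, :, 1:3], axis=(1, 2))
        sacc = (ep.times >= 2.7) & (ep.times <= 3.0)
        base = (ep.times >= 1.0) & (ep.times <= 1.9)
        return dirnorm[sacc].mean() - dirnorm[base].mean()

    hp = filter_signal(exp.eeg, "highpass", 0.4)
    calib = filter_signal(exp.calibration, "highpass", 0.4)
    corrected, _ = correct_eye_artifacts(hp, calib)
    assert frontal_dir_effect(hp) > 10 * abs(frontal_dir_effect(corrected))


def test_chain_stage_order_recorded():
    cfg = SimulationConfig(n_trials=8, n_voxels=96)
    exp = generate_experiment(cfg, seed=4)
    res = preprocess_recording(exp.eeg, exp.calibration)
    assert res.stage_order == (
        "highpass+notch",
        "interpolate",
        "eye_correction",
        "car",
        "hear",
        "lowpass",
        "resample",
    )
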