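"""Synthetic center-out reaching experiments with known ground truth.

One generated "subject" emulates a single session of the visuomotor /
oculomotor center-out paradigm: 64 EEG + 6 EOG channels at 200 Hz, a
normalized cursor-distance trace at 60 Hz, 360 trials in 2 conditions
(execution ``exe``, observation ``obs``) x 4 directions, plus a calibration
recording with rest, scripted blinks and scripted saccades.

Trial timeline (seconds relative to trial start): condition cue at 2.0 s,
direction cue at 2.5 s, cursor movement onset ~ Normal(3.23, 0.18)
truncated to [2.7, 4.0] s, movement duration ~ Normal(0.49, 0.13) s.

Source activity is built from three components projected through the
spherical-head leadfield:

* a movement-related cortical potential (MRCP): an asymmetric
  Gaussian-rise / exponential-decay negativity in left primary
  sensorimotor cortex, peaking 100 ms before the cursor movement onset,
  calibrated so the most negative medial central channel reaches a
  configurable peak (-2.3 uV in ``exe``, -0.7 uV in ``obs``);
* visually evoked potentials (VEPs): occipital bumps after both cues;
* a direction-tuned parieto-occipital response phase-locked to the
  direction cue; each PO voxel has a preferred direction and responds with
  the cosine of the angle between trial and preferred direction.

EEG = leadfield @ sources + spatially correlated pink noise + a fixed,
frontally dominant mixing of the eye-artifact sources. All randomness
derives from a single integer seed; identical (config, seed) gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit
from scipy.stats import truncnorm

from .core import (
    CONDITIONS,
    DIRECTIONS,
    DIRECTION_ANGLES,
    Leadfield,
    Recording,
)
from .leadfield import build_leadfield, central_channels

EOG_CHANNELS = (
    "EOG-sup-L",
    "EOG-inf-L",
    "EOG-sup-R",
    "EOG-inf-R",
    "EOG-canthus-L",
    "EOG-canthus-R",
)

# EOG channel composition of the three artifact sources
# (horizontal gaze, vertical gaze, blink); rows follow EOG_CHANNELS.
_EOG_MIX = np.array(
    [
        [0.0, 0.5, 0.9],
        [0.0, -0.5, 0.1],
        [0.0, 0.5, 0.9],
        [0.0, -0.5, 0.1],
        [-0.5, 0.0, 0.15],
        [0.5, 0.0, 0.15],
    ]
)


@dataclass
class SimulationConfig:
    """Study conditions of the emulated experiment."""

    n_trials: int = 360
    n_channels: int = 64
    n_voxels: int = 200
    fs_eeg: float = 200.0
    fs_cursor: float = 60.0

    trial_len: float = 6.0
    trial_spacing: float = 6.5
    t_condition_cue: float = 2.0
    t_direction_cue: float = 2.5

    onset_mean: float = 3.23
    onset_sd: float = 0.18
    onset_min: float = 2.7
    onset_max: float = 4.0
    duration_mean: float = 0.49
    duration_sd: float = 0.13
    duration_min: float = 0.2
    duration_max: float = 1.0

    # channel-space calibration targets (uV)
    mrcp_peak_exe: float = -2.3
    mrcp_peak_obs: float = -0.7
    mrcp_peak_lead: float = 0.1     # peak this many s before movement onset
    mrcp_rise_sd: float = 0.12      # steep negative deflection (~0.4 s rise)
    mrcp_decay_tau: float = 0.25
    amp_jitter_sd: float = 0.15     # trial-to-trial MRCP gain variability

    vep_amp: float = 2.0
    vep_latency: float = 0.12
    vep_sd: float = 0.08
    dir_amp: float = 0.5
    dir_latency: float = 0.35
    dir_sd: float = 0.08

    noise_rms: float = 4.0          # correlated pink noise, uV per channel
    sensor_noise_rms: float = 0.8
    n_noise_sources: int = 24
    eog_noise_rms: float = 2.0

    cursor_noise_sd: float = 0.008
    cursor_offset_mean: float = 0.02
    cursor_offset_sd: float = 0.01

    saccade_latency: float = 0.19
    blink_rate: float = 0.05        # blinks per second during the task
    heog_amp: float = 35.0          # uV per unit gaze deflection
    veog_amp: float = 25.0
    blink_amp: float = 120.0
    artifact_gain: float = 1.0      # scales EEG contamination (0 = clean)

    calib_duration: float = 120.0
    calib_rest_end: float = 40.0
    calib_blink_end: float = 80.0

    leadfield_seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Experiment:
    """One synthetic subject: recordings, trial table and ground truth."""

    eeg: Recording            # 64 EEG + 6 EOG channels at fs_eeg
    cursor: Recording         # normalized cursor distance at fs_cursor
    trials: pd.DataFrame
    calibration: Recording
    leadfield: Leadfield
    config: SimulationConfig
    components: dict[str, np.ndarray] | None = None


# ----------------------------------------------------------------- sources


@dataclass
class SourceModel:
    """Voxel sets, moment patterns and calibrated gains for one leadfield."""

    leadfield: Leadfield
    mrcp_voxels: np.ndarray
    mrcp_moments: np.ndarray      # V x 3 unit moments (inward radial)
    scale_exe: float
    scale_obs: float
    vep_voxels: np.ndarray
    vep_moments: np.ndarray
    scale_vep: float
    dir_voxels: np.ndarray
    dir_pref_angle: np.ndarray    # preferred direction per dir voxel
    scale_dir: float


def _radial_moments(lf: Leadfield, voxels: np.ndarray, inward: bool) -> np.ndarray:
    m = np.zeros((lf.n_voxels, 3))
    pos = lf.voxel_positions[voxels]
    rhat = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    m[voxels] = -rhat if inward else rhat
    return m


def _project(lf: Leadfield, moments: np.ndarray) -> np.ndarray:
    """Channel pattern of a static moment field (V x 3) -> (C,)."""
    return lf.gain @ moments.reshape(-1)


def build_source_model(lf: Leadfield, cfg: SimulationConfig) -> SourceModel:
    """Calibrate source amplitudes against channel-space targets."""
    central = central_channels(lf)

    mrcp_vox = lf.roi_voxels("SM1-L")
    if mrcp_vox.size == 0:
        raise ValueError("leadfield has no SM1-L voxels for the MRCP source")
    m_mrcp = _radial_moments(lf, mrcp_vox, inward=True) / mrcp_vox.size
    p = _project(lf, m_mrcp)
    peak = p[central].min()  # most negative central channel
    scale_exe = cfg.mrcp_peak_exe / peak
    scale_obs = cfg.mrcp_peak_obs / peak

    u = lf.voxel_positions / np.linalg.norm(
        lf.voxel_positions, axis=1, keepdims=True
    )
    vep_vox = np.flatnonzero(u[:, 1] < -0.55)
    m_vep = _radial_moments(lf, vep_vox, inward=False) / max(vep_vox.size, 1)
    q = _project(lf, m_vep)
    scale_vep = cfg.vep_amp / np.abs(q).max()

    dir_vox = np.flatnonzero(np.isin(lf.roi_labels, ["PO-L", "PO-R"]))
    golden = (1 + np.sqrt(5)) / 2
    pref = 2 * np.pi * np.mod(np.arange(dir_vox.size) / golden, 1.0)
    m_dir = np.zeros((lf.n_voxels, 3))
    pos = lf.voxel_positions[dir_vox]
    rhat = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    m_dir[dir_vox] = np.cos(pref)[:, None] * rhat / dir_vox.size
    r = _project(lf, m_dir)  # pattern for a rightward (angle 0) trial
    scale_dir = cfg.dir_amp / np.abs(r).max()

    return SourceModel(
        leadfield=lf,
        mrcp_voxels=mrcp_vox,
        mrcp_moments=m_mrcp,
        scale_exe=scale_exe,
        scale_obs=scale_obs,
        vep_voxels=vep_vox,
        vep_moments=m_vep,
        scale_vep=scale_vep,
        dir_voxels=dir_vox,
        dir_pref_angle=pref,
        scale_dir=scale_dir,
    )


def mrcp_waveform(t: np.ndarray, peak_time: float, rise_sd: float, decay_tau: float) -> np.ndarray:
    """Unit-peak asymmetric MRCP template (positive; sign lives in the
    inward dipole orientation)."""
    w = np.where(
        t < peak_time,
        np.exp(-0.5 * ((t - peak_time) / rise_sd) ** 2),
        np.exp(-(t - peak_time) / decay_tau),
    )
    return w


def _bump(t: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sd) ** 2)


def simulate_trial_sources(
    trial: pd.Series,
    cfg: SimulationConfig,
    model: SourceModel,
) -> np.ndarray:
    """Source time courses for one trial, ``n_voxels x 3 x n_times``.

    ``trial`` must provide ``condition``, ``direction`` and a
    trial-relative ``truth_move_onset`` (an absolute ``t_trial_start`` is
    subtracted when present); an optional ``mrcp_gain`` column carries
    trial-to-trial amplitude variability so that the function stays
    deterministic given the trial row.
    """
    if trial["direction"] not in DIRECTIONS:
        raise ValueError(f"unknown direction {trial['direction']!r}")
    if trial["condition"] not in CONDITIONS:
        raise ValueError(f"unknown condition {trial['condition']!r}")

    lf = model.leadfield
    n_t = int(round(cfg.trial_len * cfg.fs_eeg))
    t = np.arange(n_t) / cfg.fs_eeg
    onset = float(trial["truth_move_onset"])
    if "t_trial_start" in trial.index:
        onset -= float(trial["t_trial_start"])
    gain = float(trial.get("mrcp_gain", 1.0))

    src = np.zeros((lf.n_voxels, 3, n_t))

    scale = model.scale_exe if trial["condition"] == "exe" else model.scale_obs
    w = mrcp_waveform(
        t, onset - cfg.mrcp_peak_lead, cfg.mrcp_rise_sd, cfg.mrcp_decay_tau
    )
    src += model.mrcp_moments[:, :, None] * (scale * gain * w)[None, None, :]

    vep = _bump(t, cfg.t_condition_cue + cfg.vep_latency, cfg.vep_sd) + _bump(
        t, cfg.t_direction_cue + cfg.vep_latency, cfg.vep_sd
    )
    src += model.vep_moments[:, :, None] * (model.scale_vep * vep)[None, None, :]

    theta = DIRECTION_ANGLES[trial["direction"]]
    tuning = np.cos(theta - model.dir_pref_angle) / model.dir_voxels.size
    pos = lf.voxel_positions[model.dir_voxels]
    rhat = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    bump = _bump(t, cfg.t_direction_cue + cfg.dir_latency, cfg.dir_sd)
    src[model.dir_voxels] += (
        (tuning[:, None] * rhat)[:, :, None]
        * (model.scale_dir * bump)[None, None, :]
    )
    return src


# ------------------------------------------------------------------ cursor


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_cursor_trajectory(
    direction: str,
    onset: float,
    duration: float,
    fs: float,
    noise_sd: float = 0.0,
    length: float | None = None,
    baseline_offset: float = 0.0,
    rng: np.random.Generator | None = None,
    return_time: float | None = None,
) -> np.ndarray:
    """Normalized cursor-origin distance trace for one trial.

    The distance rises 0 -> 1 along a minimum-jerk profile starting at
    ``onset`` (s, trace-relative) and lasting ``duration``; an optional
    return movement brings it back to baseline at ``return_time``. Smooth
    jitter of standard deviation ``noise_sd`` plus a constant
    ``baseline_offset`` emulate the imperfect resting position.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    if length is None:
        length = onset + duration + 1.0
    n = int(round(length * fs))
    t = np.arange(n) / fs
    trace = minimum_jerk((t - onset) / duration)
    if return_time is not None and return_time > onset + duration:
        trace = trace - minimum_jerk((t - return_time) / 0.4)
    trace = trace + baseline_offset
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        jitter = gaussian_filter1d(rng.standard_normal(n), sigma=0.1 * fs)
        sd = jitter.std()
        if sd > 0:
            trace = trace + jitter * (noise_sd / sd)
    return trace


# --------------------------------------------------------------- artifacts


def blink_wave(t: np.ndarray, blink_times: np.ndarray, width: float = 0.25) -> np.ndarray:
    """Sum of unit raised-cosine blink pulses."""
    out = np.zeros_like(t)
    for bt in np.atleast_1d(blink_times):
        u = (t - bt) / width
        m = (u >= 0) & (u <= 1)
        out[m] += 0.5 * (1 - np.cos(2 * np.pi * u[m]))
    return out


def contamination_topographies(
    channel_positions: np.ndarray, gain: float = 1.0
) -> np.ndarray:
    """Fixed ``n_eeg x 3`` mixing of (heog, veog, blink) into EEG channels.

    Strength falls off exponentially with distance from the front of the
    head; the horizontal component is antisymmetric across the midline, as
    the rotating corneo-retinal dipole is.
    """
    u = channel_positions / np.linalg.norm(
        channel_positions, axis=1, keepdims=True
    )
    base = np.exp((u[:, 1] - 1.0) / 0.25)
    topo = np.column_stack([0.4 * base * u[:, 0], 0.25 * base, 0.3 * base])
    return gain * topo


def simulate_eye_artifacts(
    gaze: np.ndarray,
    blink_times: np.ndarray,
    cfg: SimulationConfig,
    channel_positions: np.ndarray,
    fs: float,
) -> tuple[np.ndarray, np.ndarray]:
    """EOG channels and EEG contamination from a gaze trace.

    ``gaze`` is ``2 x T`` (horizontal, vertical; unit = one target
    distance). Returns ``(eog, contamination)`` with shapes ``6 x T`` and
    ``n_eeg x T``. Sign convention: a rightward saccade makes the
    horizontal EOG derivative (right minus left outer canthus) positive.
    """
    gaze = np.atleast_2d(gaze)
    t = np.arange(gaze.shape[1]) / fs
    sources = np.vstack(
        [
            cfg.heog_amp * gaze[0],
            cfg.veog_amp * gaze[1],
            cfg.blink_amp * blink_wave(t, np.asarray(blink_times)),
        ]
    )
    eog = _EOG_MIX @ sources
    topo = contamination_topographies(channel_positions, cfg.artifact_gain)
    return eog, topo @ sources


def _gaze_trace(
    trial: pd.Series, cfg: SimulationConfig, n: int, fs: float
) -> np.ndarray:
    """Catch-up saccade toward the target, return saccade near trial end."""
    t = np.arange(n) / fs
    theta = DIRECTION_ANGLES[trial["direction"]]
    t_sac = cfg.t_direction_cue + cfg.saccade_latency
    profile = expit((t - t_sac) / 0.012) - expit(
        (t - (cfg.trial_len - 0.5)) / 0.012
    )
    return np.vstack([np.cos(theta) * profile, np.sin(theta) * profile])


# ------------------------------------------------------------------- noise


def _eog_sensor_noise(
    rng: np.random.Generator, shape: tuple, fs: float, rms: float
) -> np.ndarray:
    """Band-limited (~8 Hz) periocular sensor noise."""
    if rms <= 0:
        return np.zeros(shape)
    w = gaussian_filter1d(rng.standard_normal(shape), sigma=0.01 * fs, axis=-1)
    sd = w.std()
    return w * (rms / sd) if sd > 0 else w


def _pink_noise(rng: np.random.Generator, n_src: int, n_samp: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise, one row per source."""
    white = rng.standard_normal((n_src, n_samp))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    f[0] = f[1] if len(f) > 1 else 1.0
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n=n_samp, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out


def _correlated_noise(
    rng: np.random.Generator,
    lf: Leadfield,
    n_samp: int,
    cfg: SimulationConfig,
) -> np.ndarray:
    """Pink noise mixed through random dipole topographies + sensor noise."""
    k = cfg.n_noise_sources
    vox = rng.integers(0, lf.n_voxels, size=k)
    moments = rng.standard_normal((k, 3))
    moments /= np.linalg.norm(moments, axis=1, keepdims=True)
    g3 = lf.gain3()
    topo = np.stack([g3[:, v] @ m for v, m in zip(vox, moments)], axis=1)
    topo /= np.linalg.norm(topo, axis=0, keepdims=True)
    mixed = topo @ _pink_noise(rng, k, n_samp, cfg.fs_eeg)
    rms = np.sqrt(np.mean(mixed**2))
    if rms > 0:
        mixed *= cfg.noise_rms / rms
    mixed += cfg.sensor_noise_rms * rng.standard_normal(mixed.shape)
    return mixed


# -------------------------------------------------------------- experiment


def _balanced_cells(n_trials: int, rng: np.random.Generator) -> pd.DataFrame:
    """Condition x direction assignment, as balanced as n_trials allows.

    If ``n_trials`` is not divisible by 8, the remainder is distributed one
    trial at a time over the cells in fixed (condition, direction) order.
    """
    if n_trials < 8:
        raise ValueError("need at least 8 trials (one per cell)")
    cells = [(c, d) for c in CONDITIONS for d in DIRECTIONS]
    reps = n_trials // 8
    rem = n_trials % 8
    rows = []
    for i, (c, d) in enumerate(cells):
        rows += [(c, d)] * (reps + (1 if i < rem else 0))
    rows = [rows[i] for i in rng.permutation(len(rows))]
    return pd.DataFrame(rows, columns=["condition", "direction"])


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def make_trial_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    tab = _balanced_cells(cfg.n_trials, rng)
    n = len(tab)
    tab.insert(0, "trial_id", np.arange(n))
    t0 = np.arange(n) * cfg.trial_spacing
    tab["t_trial_start"] = t0
    tab["t_condition_cue"] = t0 + cfg.t_condition_cue
    tab["t_direction_cue"] = t0 + cfg.t_direction_cue
    tab["truth_move_onset"] = t0 + _truncnorm(
        rng, cfg.onset_mean, cfg.onset_sd, cfg.onset_min, cfg.onset_max, n
    )
    tab["truth_move_duration"] = _truncnorm(
        rng,
        cfg.duration_mean,
        cfg.duration_sd,
        cfg.duration_min,
        cfg.duration_max,
        n,
    )
    tab["mrcp_gain"] = np.clip(
        1.0 + cfg.amp_jitter_sd * rng.standard_normal(n), 0.3, None
    )
    tab["cursor_offset"] = np.abs(
        rng.normal(cfg.cursor_offset_mean, cfg.cursor_offset_sd, n)
    )
    tab["detected_onset"] = np.nan
    tab["detected_offset"] = np.nan
    tab["duration"] = np.nan
    tab["outlier"] = False
    return tab


def generate_experiment(
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    return_components: bool = False,
) -> Experiment:
    """Generate one synthetic subject (task + calibration recordings)."""
    if cfg is None:
        cfg = SimulationConfig()
    ss = np.random.SeedSequence(seed)
    rng_trials, rng_noise, rng_cursor, rng_eye, rng_calib = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    lf_seed = cfg.leadfield_seed if cfg.leadfield_seed is not None else seed
    lf = build_leadfield(cfg.n_channels, cfg.n_voxels, seed=lf_seed)
    model = build_source_model(lf, cfg)
    trials = make_trial_table(cfg, rng_trials)
    n = len(trials)

    fs = cfg.fs_eeg
    n_total = int(round(n * cfg.trial_spacing * fs))
    n_trial = int(round(cfg.trial_len * fs))
    clean = np.zeros((cfg.n_channels, n_total))
    contam = np.zeros_like(clean)
    eog = np.zeros((6, n_total))

    fs_c = cfg.fs_cursor
    nc_total = int(round(n * cfg.trial_spacing * fs_c))
    nc_seg = int(round(cfg.trial_spacing * fs_c))
    cursor = np.zeros(nc_total)

    g3 = lf.gain3().reshape(cfg.n_channels, -1)
    events: list[tuple[str, float]] = []
    for _, trial in trials.iterrows():
        i0 = int(round(trial["t_trial_start"] * fs))
        src = simulate_trial_sources(trial, cfg, model)
        clean[:, i0 : i0 + n_trial] += g3 @ src.reshape(-1, n_trial)

        gaze = _gaze_trace(trial, cfg, n_trial, fs)
        n_blinks = rng_eye.poisson(cfg.blink_rate * cfg.trial_len)
        btimes = rng_eye.uniform(0, cfg.trial_len - 0.3, size=n_blinks)
        e, c = simulate_eye_artifacts(
            gaze, btimes, cfg, lf.channel_positions, fs
        )
        eog[:, i0 : i0 + n_trial] += e
        contam[:, i0 : i0 + n_trial] += c

        j0 = int(round(trial["t_trial_start"] * fs_c))
        cursor[j0 : j0 + nc_seg] = simulate_cursor_trajectory(
            trial["direction"],
            onset=trial["truth_move_onset"] - trial["t_trial_start"],
            duration=trial["truth_move_duration"],
            fs=fs_c,
            noise_sd=cfg.cursor_noise_sd,
            length=cfg.trial_spacing,
            baseline_offset=trial["cursor_offset"],
            rng=rng_cursor,
            return_time=cfg.trial_len,
        )

        t0 = trial["t_trial_start"]
        events.append(("trial_start", t0))
        events.append((f"condition_cue/{trial['condition']}", t0 + cfg.t_condition_cue))
        events.append((f"direction_cue/{trial['direction']}", t0 + cfg.t_direction_cue))

    noise = _correlated_noise(rng_noise, lf, n_total, cfg)
    eeg_data = clean + noise + contam
    eog_noisy = eog + _eog_sensor_noise(rng_eye, eog.shape, fs, cfg.eog_noise_rms)

    names = [f"E{i + 1:02d}" for i in range(cfg.n_channels)] + list(EOG_CHANNELS)
    types = ["eeg"] * cfg.n_channels + ["eog"] * 6
    positions = np.vstack(
        [lf.channel_positions, np.full((6, 3), np.nan)]
    )
    eeg_rec = Recording(
        data=np.vstack([eeg_data, eog_noisy]),
        fs=fs,
        channel_names=names,
        channel_types=types,
        events=events,
        channel_positions=positions,
    )
    cursor_rec = Recording(
        data=cursor[None, :],
        fs=fs_c,
        channel_names=["cursor-distance"],
        channel_types=["cursor"],
        events=[e for e in events if e[0] == "trial_start"],
    )
    calib_rec = _generate_calibration(cfg, lf, rng_calib)

    components = None
    if return_components:
        components = {"clean": clean, "noise": noise, "contamination": contam}
    return Experiment(
        eeg=eeg_rec,
        cursor=cursor_rec,
        trials=trials,
        calibration=calib_rec,
        leadfield=lf,
        config=cfg,
        components=components,
    )


def _generate_calibration(
    cfg: SimulationConfig, lf: Leadfield, rng: np.random.Generator
) -> Recording:
    """Rest + scripted blinks + scripted saccades (experimental blocks 2/4)."""
    fs = cfg.fs_eeg
    n = int(round(cfg.calib_duration * fs))
    t = np.arange(n) / fs

    blink_times = np.arange(cfg.calib_rest_end + 1.0, cfg.calib_blink_end - 1.0, 2.5)
    gaze = np.zeros((2, n))
    sacc_dirs: list[str] = []
    sacc_times = np.arange(cfg.calib_blink_end + 1.0, cfg.calib_duration - 1.5, 2.5)
    for i, st in enumerate(sacc_times):
        d = DIRECTIONS[i % 4]
        sacc_dirs.append(d)
        theta = DIRECTION_ANGLES[d]
        prof = expit((t - st) / 0.012) - expit((t - st - 1.2) / 0.012)
        gaze[0] += np.cos(theta) * prof
        gaze[1] += np.sin(theta) * prof

    eog, contam = simulate_eye_artifacts(
        gaze, blink_times, cfg, lf.channel_positions, fs
    )
    noise = _correlated_noise(rng, lf, n, cfg)
    eeg = noise + contam
    eog = eog + _eog_sensor_noise(rng, eog.shape, fs, cfg.eog_noise_rms)

    events: list[tuple[str, float]] = [("calib_rest_start", 0.0)]
    events += [("calib_blink", float(bt)) for bt in blink_times]
    events += [
        (f"calib_saccade/{d}", float(st)) for d, st in zip(sacc_dirs, sacc_times)
    ]
    names = [f"E{i + 1:02d}" for i in range(cfg.n_channels)] + list(EOG_CHANNELS)
    types = ["eeg"] * cfg.n_channels + ["eog"] * 6
    return Recording(
        data=np.vstack([eeg, eog]),
        fs=fs,
        channel_names=names,
        channel_types=types,
        events=events,
        channel_positions=np.vstack(
            [lf.channel_positions, np.full((6, 3), np.nan)]
        ),
    )
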