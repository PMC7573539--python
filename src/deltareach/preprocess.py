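"""Preprocessing chain: raw recording -> delta-band, artifact-corrected EEG.

Stage order is fixed: high-pass + notch -> spherical interpolation of bad
channels -> eye-artifact subtraction (fitted on calibration data only) ->
common average reference -> HEAR transient-artifact suppression ->
low-pass (delta band) -> resample. ``preprocess_recording`` enforces this
order; the individual stages are usable on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.spatial import Delaunay
from scipy.special import eval_legendre

from .core import Recording
from .simulate import EOG_CHANNELS


# ----------------------------------------------------------------- filters


def filter_signal(
    rec: Recording,
    kind: str,
    cutoff: float,
    order: int = 4,
    zero_phase: bool = True,
    notch_q: float = 30.0,
) -> Recording:
    """Butterworth high/low-pass or IIR notch filter (zero-phase default).

    Zero-phase filtering runs the filter forward and backward
    (``sosfiltfilt``), squaring the magnitude response and cancelling the
    phase, so symmetric transients keep their latency.
    """
    nyq = rec.fs / 2
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    out = rec.copy()
    if kind == "notch":
        b, a = signal.iirnotch(cutoff, Q=notch_q, fs=rec.fs)
        if zero_phase:
            out.data = signal.filtfilt(b, a, out.data, axis=1)
        else:
            out.data = signal.lfilter(b, a, out.data, axis=1)
        return out
    if kind not in ("highpass", "lowpass"):
        raise ValueError(f"unknown filter kind {kind!r}")
    sos = signal.butter(order, cutoff, btype=kind, fs=rec.fs, output="sos")
    if zero_phase:
        out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    else:
        out.data = signal.sosfilt(sos, out.data, axis=1)
    return out


def resample_signal(rec: Recording, fs_new: float) -> Recording:
    """Anti-aliased polyphase resampling; event times (seconds) unchanged."""
    if fs_new >= rec.fs:
        raise ValueError("fs_new must be below the current sampling rate")
    from fractions import Fraction

    frac = Fraction(fs_new / rec.fs).limit_denominator(1000)
    out = rec.copy()
    out.data = signal.resample_poly(
        rec.data, frac.numerator, frac.denominator, axis=1, padtype="line"
    )
    out.fs = fs_new
    out.events = [
        (lbl, t) for lbl, t in rec.events if t <= out.data.shape[1] / fs_new
    ]
    return out


# ----------------------------------------------- spherical interpolation


def _spline_g(cosang: np.ndarray, stiffness: int = 4, n_terms: int = 50) -> np.ndarray:
    """Spherical-spline kernel g(cos) of Perrin et al."""
    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n**stiffness * (n + 1) ** stiffness)
    shape = cosang.shape
    p = np.stack([eval_legendre(k, cosang.ravel()) for k in n], axis=0)
    return (coef @ p).reshape(shape) / (4 * np.pi)


def interpolate_channels(
    rec: Recording,
    bad_channels: list[str],
    channel_positions: np.ndarray | None = None,
) -> Recording:
    """Replace bad channels by spherical-spline estimates from good ones."""
    if not bad_channels:
        return rec.copy()
    unknown = set(bad_channels) - set(rec.channel_names)
    if unknown:
        raise ValueError(f"bad channels not in recording: {sorted(unknown)}")
    if channel_positions is None:
        channel_positions = rec.channel_positions
    if channel_positions is None:
        raise ValueError("channel positions required for interpolation")

    eeg = rec.picks("eeg")
    bad = np.array([rec.channel_names.index(b) for b in bad_channels])
    good = np.array([i for i in eeg if i not in bad])
    if good.size < 4:
        raise ValueError("need at least 4 good EEG channels")

    pos = channel_positions / np.linalg.norm(
        channel_positions, axis=1, keepdims=True
    )
    g_gg = _spline_g(pos[good] @ pos[good].T)
    g_bg = _spline_g(pos[bad] @ pos[good].T)

    n_good = good.size
    a = np.zeros((n_good + 1, n_good + 1))
    a[:n_good, :n_good] = g_gg
    a[:n_good, n_good] = 1.0
    a[n_good, :n_good] = 1.0
    rhs = np.zeros((n_good + 1, rec.n_samples))
    rhs[:n_good] = rec.data[good]
    sol = np.linalg.solve(a, rhs)
    interp = g_bg @ sol[:n_good] + sol[n_good]

    out = rec.copy()
    out.data[bad] = interp
    return out


# ------------------------------------------------------- eye artifacts


@dataclass
class EyeModel:
    """Regression/subspace eye-artifact model fitted on calibration data.

    Regressors: the three EOG derivatives (horizontal = right - left outer
    canthus; vertical = superior - inferior, per eye) plus the time course
    of the first principal component of the EOG channels during scripted
    calibration blinks. ``coef`` maps the 4 regressors to EEG channels.
    """

    coef: np.ndarray                 # n_eeg x 4
    blink_weights: np.ndarray        # 6 (EOG-channel spatial filter)
    calib_variance: np.ndarray       # per EEG channel, after correction+CAR
    eog_names: tuple = EOG_CHANNELS


def eog_derivatives(rec: Recording) -> np.ndarray:
    """``3 x T``: horizontal, vertical-left, vertical-right EOG derivatives."""
    get = rec.get_channel
    heog = get("EOG-canthus-R") - get("EOG-canthus-L")
    veog_l = get("EOG-sup-L") - get("EOG-inf-L")
    veog_r = get("EOG-sup-R") - get("EOG-inf-R")
    return np.vstack([heog, veog_l, veog_r])


def _blink_spatial_filter(calib: Recording, window: float = 0.4) -> np.ndarray:
    """First principal component of EOG activity in calibration blink
    segments; sign fixed positive on the superior electrodes."""
    eogd = calib.data[calib.picks("eog")]
    segs = []
    for lbl, t in calib.events:
        if lbl == "calib_blink":
            i0 = int(t * calib.fs)
            segs.append(eogd[:, i0 : i0 + int(window * calib.fs)])
    if not segs:
        raise ValueError("calibration recording contains no blink events")
    x = np.hstack(segs)
    x = x - x.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    w = u[:, 0]
    sup = [list(EOG_CHANNELS).index(n) for n in ("EOG-sup-L", "EOG-sup-R")]
    if w[sup].sum() < 0:
        w = -w
    return w


def _eye_regressors(rec: Recording, blink_weights: np.ndarray) -> np.ndarray:
    eogd = rec.data[rec.picks("eog")]
    return np.vstack([eog_derivatives(rec), blink_weights @ eogd])


def fit_eye_model(calib: Recording, min_duration: float = 10.0) -> EyeModel:
    if calib.duration < min_duration:
        raise ValueError(
            f"calibration shorter than required minimum {min_duration}s"
        )
    w = _blink_spatial_filter(calib)
    z = _eye_regressors(calib, w)
    eeg = calib.data[calib.picks("eeg")]
    coef = np.linalg.lstsq(z.T, eeg.T, rcond=None)[0].T
    corrected = eeg - coef @ z
    corrected = corrected - corrected.mean(axis=0, keepdims=True)  # CAR view
    return EyeModel(
        coef=coef, blink_weights=w, calib_variance=corrected.var(axis=1)
    )


def correct_eye_artifacts(
    rec: Recording,
    calibration: Recording | EyeModel,
    min_duration: float = 10.0,
) -> tuple[Recording, EyeModel]:
    """Subtract the calibrated eye-artifact subspace from the EEG channels.

    EOG channels are retained unmodified (the behavioral analysis needs
    them). The model is always fitted on calibration data, never on the
    task recording itself.
    """
    model = (
        calibration
        if isinstance(calibration, EyeModel)
        else fit_eye_model(calibration, min_duration)
    )
    z = _eye_regressors(rec, model.blink_weights)
    out = rec.copy()
    eeg = rec.picks("eeg")
    out.data[eeg] = out.data[eeg] - model.coef @ z
    return out, model


# ------------------------------------------------------------------- CAR


def apply_car(rec: Recording) -> Recording:
    """Common average reference over the EEG channels."""
    eeg = rec.picks("eeg")
    if eeg.size < 2:
        raise ValueError("CAR needs at least 2 EEG channels")
    out = rec.copy()
    out.data[eeg] -= out.data[eeg].mean(axis=0, keepdims=True)
    return out


# ------------------------------------------------------------------ HEAR


def electrode_adjacency(positions: np.ndarray) -> list[np.ndarray]:
    """Neighbor lists from Delaunay triangulation of the projected montage."""
    pos = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    tri = Delaunay(pos[:, :2])
    neigh = [set() for _ in range(len(pos))]
    for simplex in tri.simplices:
        for i in simplex:
            neigh[i].update(j for j in simplex if j != i)
    return [np.array(sorted(s), dtype=int) for s in neigh]


def hear_correct(
    rec: Recording,
    calib_variance: np.ndarray,
    adjacency: list[np.ndarray] | None = None,
    window: float = 0.25,
    r_saturate: float = 5.0,
) -> Recording:
    """High-variance electrode artifact removal.

    The sliding-window variance of each EEG channel is compared with its
    calibration variance. The variance ratio maps to an artifact
    probability through a linear ramp, ``p = clip((ratio - 1) /
    (r_saturate - 1), 0, 1)`` (a ratio of 3 with the default saturation of
    5 gives p = 0.5), and the output is the probability-weighted mix of the
    channel with the mean of its spatial neighbors.
    """
    eeg = rec.picks("eeg")
    calib_variance = np.asarray(calib_variance, dtype=float)
    if calib_variance.shape[0] != eeg.size:
        raise ValueError("calibration variance must have one entry per EEG channel")
    if np.any(calib_variance <= 0):
        raise ValueError("calibration variances must be positive")
    if adjacency is None:
        if rec.channel_positions is None:
            raise ValueError("adjacency or channel positions required")
        adjacency = electrode_adjacency(rec.channel_positions[eeg])

    x = rec.data[eeg]
    n_w = max(int(round(window * rec.fs)), 2)
    kernel = np.ones(n_w) / n_w
    # sliding variance about zero: signals are high-passed upstream
    var = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="same"), 1, x**2
    )
    ratio = var / calib_variance[:, None]
    p = np.clip((ratio - 1.0) / (r_saturate - 1.0), 0.0, 1.0)

    neighbor_mean = np.empty_like(x)
    for i, nb in enumerate(adjacency):
        neighbor_mean[i] = x[nb].mean(axis=0)
    out = rec.copy()
    out.data[eeg] = (1.0 - p) * x + p * neighbor_mean
    return out


# --------------------------------------------------------------- pipeline


@dataclass
class PreprocessConfig:
    highpass: float = 0.4
    notch: float = 50.0
    filter_order: int = 4
    lowpass: float = 3.0
    fs_out: float = 10.0
    bad_channels: list[str] = field(default_factory=list)
    hear_window: float = 0.25
    hear_saturate: float = 5.0
    eye_min_duration: float = 10.0


@dataclass
class PreprocessResult:
    delta: Recording          # delta band at fs_out
    broadband: Recording      # post-HEAR broadband at the input rate
    calib_delta: Recording    # calibration through the same chain
    eye_model: EyeModel
    stage_order: tuple


def preprocess_recording(
    task: Recording,
    calibration: Recording,
    cfg: PreprocessConfig | None = None,
) -> PreprocessResult:
    """Run the full chain on a task recording and its calibration block."""
    if cfg is None:
        cfg = PreprocessConfig()
    stages = []

    def _front(rec: Recording) -> Recording:
        out = filter_signal(rec, "highpass", cfg.highpass, cfg.filter_order)
        if cfg.notch and cfg.notch < rec.fs / 2:
            out = filter_signal(out, "notch", cfg.notch)
        return interpolate_channels(out, cfg.bad_channels)

    calib_f = _front(calibration)
    stages.append("highpass+notch")
    stages.append("interpolate")
    eye_model = fit_eye_model(calib_f, cfg.eye_min_duration)

    task_f = _front(task)
    task_c, _ = correct_eye_artifacts(task_f, eye_model)
    calib_c, _ = correct_eye_artifacts(calib_f, eye_model)
    stages.append("eye_correction")

    task_c = apply_car(task_c)
    calib_c = apply_car(calib_c)
    stages.append("car")

    adjacency = electrode_adjacency(
        task.channel_positions[task.picks("eeg")]
    )
    task_h = hear_correct(
        task_c,
        eye_model.calib_variance,
        adjacency,
        cfg.hear_window,
        cfg.hear_saturate,
    )
    calib_h = hear_correct(
        calib_c,
        eye_model.calib_variance,
        adjacency,
        cfg.hear_window,
        cfg.hear_saturate,
    )
    stages.append("hear")

    delta = filter_signal(task_h, "lowpass", cfg.lowpass, cfg.filter_order)
    calib_delta = filter_signal(calib_h, "lowpass", cfg.lowpass, cfg.filter_order)
    stages.append("lowpass")
    delta = resample_signal(delta, cfg.fs_out)
    calib_delta = resample_signal(calib_delta, cfg.fs_out)
    stages.append("resample")

    expected = (
        "highpass+notch",
        "interpolate",
        "eye_correction",
        "car",
        "hear",
        "lowpass",
        "resample",
    )
    assert tuple(stages) == expected, "preprocessing stage order violated"
    return PreprocessResult(
        delta=delta,
        broadband=task_h,
        calib_delta=calib_delta,
        eye_model=eye_model,
        stage_order=expected,
    )
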