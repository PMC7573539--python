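"""Behavioral event detection and statistics.

Covers cursor movement onset/offset detection (threshold + refined
tangent rule), robust outlier flagging of trials, direction-specific eye
movement (catch-up saccade) onsets from EOG derivatives, and the two-way
repeated-measures ANOVA with Bonferroni post-hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .core import CONDITIONS, DIRECTIONS, Recording
from .preprocess import eog_derivatives

#: 1 / Phi^-1(0.75): scales the median absolute deviation to a standard
#: deviation under normality.
ROBUST_SCALE = float(1.0 / stats.norm.ppf(0.75))


def robust_zscore(x: np.ndarray) -> np.ndarray:
    """|x - median| / (1.4826 * MAD).

    If the MAD is zero while some values deviate from the median, those
    values get an infinite score (and are therefore always flagged).
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.where(x == med, 0.0, np.inf)
    return np.abs(x - med) / (ROBUST_SCALE * mad)


@dataclass
class OnsetDetectionParams:
    """Parameters of the cursor onset/offset detector.

    The triangular smoothing window is specified as ``smooth_taps`` taps at
    the reference rate ``smooth_fs`` (i.e. a fixed duration in seconds);
    at other sampling rates an odd tap count covering the same duration is
    used.
    """

    baseline_window: float = 1.0      # last second of the preparation period
    threshold: float = 0.05           # initial onset, normalized distance
    refine_window: float = 1.75       # s of smoothed trace before the onset
    smooth_taps: int = 63
    smooth_fs: float = 200.0
    offset_threshold: float = 0.1     # distance-to-target
    prep_end: float = 2.5             # direction cue: end of preparation
    target_distance: float = 1.0

    def __post_init__(self):
        if min(
            self.baseline_window,
            self.threshold,
            self.refine_window,
            self.smooth_taps,
            self.offset_threshold,
        ) <= 0:
            raise ValueError("onset-detection parameters must be positive")
        if self.smooth_taps % 2 == 0:
            raise ValueError("smooth_taps must be odd")

    def taps_at(self, fs: float) -> int:
        n = int(round(self.smooth_taps * fs / self.smooth_fs))
        n = max(n, 3)
        return n if n % 2 == 1 else n + 1


@dataclass
class CursorEvents:
    onset: float
    offset: float
    duration: float
    moved: bool


def _triangular_smooth(x: np.ndarray, taps: int) -> np.ndarray:
    win = np.bartlett(taps + 2)[1:-1]
    win /= win.sum()
    return np.convolve(x, win, mode="same")


def detect_cursor_events(
    trace: np.ndarray,
    fs: float,
    params: OnsetDetectionParams | None = None,
) -> CursorEvents:
    """Detect cursor movement onset, offset and duration for one trial.

    ``trace`` is the normalized cursor-origin distance, starting at the
    trial start (t = 0). The baseline (mean over the last
    ``baseline_window`` of the preparation period) is subtracted; the
    first crossing of ``threshold`` gives an initial onset, refined by the
    tangent at the maximal finite-difference derivative of the smoothed
    trace within the preceding ``refine_window``. The offset is the first
    time the distance to the target drops below ``offset_threshold``.
    """
    if params is None:
        params = OnsetDetectionParams()
    trace = np.asarray(trace, dtype=float)
    i_prep = int(round(params.prep_end * fs))
    i_base = int(round((params.prep_end - params.baseline_window) * fs))
    if i_prep > len(trace) or i_base < 0:
        raise ValueError("trace does not cover the preparation period")
    x = trace - trace[i_base:i_prep].mean()

    # the detector operates on the smoothed trace throughout: the initial
    # threshold crossing on the raw trace would bias the tangent point into
    # the smoothing transition band
    xs = _triangular_smooth(x, params.taps_at(fs))
    above = np.flatnonzero(xs[i_prep:] > params.threshold)
    if above.size == 0:
        return CursorEvents(np.nan, np.nan, np.nan, moved=False)
    i0 = i_prep + int(above[0])
    w_start = max(i0 - int(round(params.refine_window * fs)), 0)
    win = xs[w_start : i0 + 1]
    if win.size >= 2:
        deriv = np.gradient(win, 1.0 / fs)
        i_max = int(np.argmax(deriv))  # first maximum: earliest time-point
        slope = deriv[i_max]
        if slope > 0:
            onset = (w_start + i_max) / fs - win[i_max] / slope
        else:
            onset = i0 / fs
    else:
        onset = i0 / fs

    to_target = params.target_distance - x[i0:]
    hit = np.flatnonzero(to_target < params.offset_threshold)
    if hit.size:
        offset = (i0 + int(hit[0])) / fs
        duration = offset - onset
    else:
        offset = np.nan
        duration = np.nan
    return CursorEvents(onset, offset, duration, moved=True)


def flag_outlier_trials(
    onsets: np.ndarray, durations: np.ndarray, k: float = 2.5
) -> np.ndarray:
    """Robust-z outlier mask over trial onsets (relative to trial start)
    and movement durations; a trial is an outlier if either metric exceeds
    ``k`` robust standard deviations."""
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if onsets.size < 3:
        raise ValueError("need at least 3 trials")
    return (robust_zscore(onsets) > k) | (robust_zscore(durations) > k)


def detect_eye_onset(
    rec: Recording,
    trials: pd.DataFrame,
    epoch_len: float = 4.0,
    baseline: tuple[float, float] = (1.0, 1.5),
    n_sd: float = 3.0,
    min_duration: float = 0.05,
) -> dict[str, float | None]:
    """Direction-specific eye movement onsets from averaged EOG derivatives.

    Trials sharing a direction are averaged (trial-start aligned); the
    onset is the first time after the baseline window at which the
    direction-associated, sign-corrected derivative exceeds the baseline
    mean by ``n_sd`` baseline standard deviations and stays above the
    threshold for at least ``min_duration`` (guards against isolated noise
    excursions). Returns ``None`` for a direction whose derivative never
    crosses the threshold.
    """
    fs = rec.fs
    deriv = eog_derivatives(rec)
    heog, veog = deriv[0], 0.5 * (deriv[1] + deriv[2])
    component = {
        "right": heog,
        "left": -heog,
        "up": veog,
        "down": -veog,
    }
    n_e = int(round(epoch_len * fs))
    out: dict[str, float | None] = {}
    for d in DIRECTIONS:
        starts = trials.loc[trials["direction"] == d, "t_trial_start"]
        sig = component[d]
        segs = []
        for t0 in starts:
            i0 = int(round(t0 * fs))
            if i0 + n_e <= sig.size:
                segs.append(sig[i0 : i0 + n_e])
        if not segs:
            out[d] = None
            continue
        avg = np.mean(segs, axis=0)
        b0, b1 = int(baseline[0] * fs), int(baseline[1] * fs)
        thresh = avg[b0:b1].mean() + n_sd * avg[b0:b1].std()
        above = avg[b1:] > thresh
        need = max(int(round(min_duration * fs)), 1)
        run = np.convolve(above.astype(int), np.ones(need, dtype=int), "valid")
        sustained = np.flatnonzero(run == need)
        out[d] = (b1 + int(sustained[0])) / fs if sustained.size else None
    return out


def rm_anova_two_way(values: np.ndarray) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on a complete subjects x condition
    x direction table.

    Returns a DataFrame indexed by effect (condition, direction,
    condition:direction) with columns F, df1, df2, p. Uncorrected degrees
    of freedom are used for the 4-level direction factor.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[1] != 2 or values.shape[2] != 4:
        raise ValueError("values must be subjects x 2 conditions x 4 directions")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing cells in the ANOVA table")
    n_subj = values.shape[0]
    rows = []
    for s in range(n_subj):
        for ic, c in enumerate(CONDITIONS):
            for idx, d in enumerate(DIRECTIONS):
                rows.append((s, c, d, values[s, ic, idx]))
    long = pd.DataFrame(rows, columns=["subject", "condition", "direction", "y"])
    res = AnovaRM(
        long, depvar="y", subject="subject", within=["condition", "direction"]
    ).fit()
    tab = res.anova_table
    out = pd.DataFrame(
        {
            "F": tab["F Value"].values,
            "df1": tab["Num DF"].values,
            "df2": tab["Den DF"].values,
            "p": tab["Pr > F"].values,
        },
        index=[i.lower() for i in tab.index],
    )
    return out


def posthoc_direction_ttests(values: np.ndarray) -> pd.DataFrame:
    """Paired t-tests between direction levels (averaged over conditions)
    with Bonferroni correction."""
    values = np.asarray(values, dtype=float)
    per_dir = values.mean(axis=1)  # subjects x 4
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    rows = []
    for i, j in pairs:
        t, p = stats.ttest_rel(per_dir[:, i], per_dir[:, j])
        rows.append(
            {
                "a": DIRECTIONS[i],
                "b": DIRECTIONS[j],
                "t": t,
                "p": p,
                "p_bonferroni": min(p * len(pairs), 1.0),
            }
        )
    return pd.DataFrame(rows)


def detect_all_trials(
    cursor: Recording,
    trials: pd.DataFrame,
    params: OnsetDetectionParams | None = None,
    outlier_k: float = 2.5,
) -> pd.DataFrame:
    """Run onset/offset detection for every trial and flag outliers.

    Detected times are stored as absolute recording times; the outlier
    rule operates on trial-relative onsets and durations.
    """
    if params is None:
        params = OnsetDetectionParams()
    fs = cursor.fs
    trace = cursor.data[0]
    out = trials.copy()
    seg_len = None
    starts = out["t_trial_start"].to_numpy()
    if len(starts) > 1:
        seg_len = int(round((starts[1] - starts[0]) * fs))
    for idx, row in out.iterrows():
        i0 = int(round(row["t_trial_start"] * fs))
        i1 = i0 + seg_len if seg_len else trace.size
        ev = detect_cursor_events(trace[i0:i1], fs, params)
        if ev.moved:
            out.loc[idx, "detected_onset"] = row["t_trial_start"] + ev.onset
            out.loc[idx, "detected_offset"] = row["t_trial_start"] + ev.offset
            out.loc[idx, "duration"] = ev.duration
    rel_onset = out["detected_onset"] - out["t_trial_start"]
    ok = rel_onset.notna() & out["duration"].notna()
    mask = np.zeros(len(out), dtype=bool)
    if ok.sum() >= 3:
        mask[ok.to_numpy()] = flag_outlier_trials(
            rel_onset[ok].to_numpy(), out.loc[ok, "duration"].to_numpy(), outlier_k
        )
    mask |= ~ok.to_numpy()  # no-movement trials are dropped as well
    out["outlier"] = mask
    return out
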