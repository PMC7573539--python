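"""Epoch extraction and two-pass statistical artifact rejection.

Epochs are cut under two alignments — trial start ([0.75, 4.75) s after
the start event) and cursor movement onset ([-2, 1.25) s around the
detected onset) — with a half-open sample convention, so a window of
length L at rate fs yields ``floor(L * fs)`` samples.

Artifact rejection runs on *broadband* epochs: an absolute +-200 uV
amplitude criterion, plus per-channel joint probability, kurtosis and
variance statistics thresholded at 6 / 6 / 5 robust standard deviations
across trials. The statistical criteria are applied twice (gross outliers
first, subtle outliers after recomputation); the union of all masks is
applied to the delta-band epochs downstream.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .behavior import ROBUST_SCALE
from .core import Epochs, Recording


def extract_epochs(
    rec: Recording,
    anchors: np.ndarray,
    window: tuple[float, float],
    alignment: str = "trial_start",
    band: str = "broadband",
    picks: np.ndarray | None = None,
) -> Epochs:
    """Cut one epoch per anchor time (seconds, absolute).

    The sample convention is half-open ``[a, b)``: sample k corresponds to
    time ``a + k / fs`` for ``k < floor((b - a) * fs)``.
    """
    a, b = window
    if b <= a:
        raise ValueError("window must have positive length")
    if picks is None:
        picks = rec.picks("eeg")
    n_t = int(np.floor((b - a) * rec.fs + 1e-9))
    times = a + np.arange(n_t) / rec.fs
    data = np.empty((len(anchors), len(picks), n_t))
    for k, anchor in enumerate(np.asarray(anchors, dtype=float)):
        i0 = int(round((anchor + a) * rec.fs))
        if i0 < 0 or i0 + n_t > rec.n_samples:
            raise ValueError(
                f"epoch for trial {k} (anchor {anchor:.3f}s) exceeds the "
                "recording bounds"
            )
        data[k] = rec.data[np.ix_(picks, np.arange(i0, i0 + n_t))]
    return Epochs(
        data=data,
        times=times,
        fs=rec.fs,
        alignment=alignment,
        band=band,
        channel_names=[rec.channel_names[i] for i in picks],
    )


def _robust_z_columns(stat: np.ndarray) -> np.ndarray:
    """Robust z of each column (trials x channels) across trials."""
    med = np.median(stat, axis=0)
    mad = np.median(np.abs(stat - med), axis=0)
    sigma = ROBUST_SCALE * mad
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(stat - med) / sigma
    z[:, sigma == 0] = np.where(
        stat[:, sigma == 0] == med[sigma == 0], 0.0, np.inf
    )
    return z


def _epoch_statistics(data: np.ndarray) -> dict[str, np.ndarray]:
    """Per-epoch, per-channel statistics (trials x channels)."""
    n_e, n_c, _ = data.shape
    var = data.var(axis=2)
    kurt = stats.kurtosis(data, axis=2, fisher=True, bias=True)
    # joint probability: mean log-density of the epoch's samples under a
    # Gaussian fitted to the channel's pooled distribution over all epochs
    mu = data.mean(axis=(0, 2))
    sd = data.std(axis=(0, 2))
    sd = np.where(sd == 0, 1.0, sd)
    z = (data - mu[None, :, None]) / sd[None, :, None]
    logp = -0.5 * (z**2).mean(axis=2) - np.log(sd)[None, :] - 0.5 * np.log(2 * np.pi)
    return {"jointprob": logp, "kurtosis": kurt, "variance": var}


def reject_artifact_epochs(
    epochs: Epochs,
    amplitude: float = 200.0,
    z_jointprob: float = 6.0,
    z_kurtosis: float = 6.0,
    z_variance: float = 5.0,
    n_passes: int = 2,
    min_survivors: int = 5,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Two-pass statistical rejection on broadband epochs.

    Returns ``(mask, reasons)`` where ``mask`` is True for rejected trials
    and ``reasons`` holds one mask per criterion and pass. The statistical
    thresholds are per-channel robust z-scores across trials, maximized
    over channels.
    """
    if epochs.band != "broadband":
        raise ValueError("rejection statistics require broadband epochs")
    data = epochs.data
    n = len(data)
    thresholds = {
        "jointprob": z_jointprob,
        "kurtosis": z_kurtosis,
        "variance": z_variance,
    }
    reasons: dict[str, np.ndarray] = {}
    amp = np.any(np.abs(data) > amplitude, axis=(1, 2))
    reasons["amplitude"] = amp

    total = amp.copy()
    for p in range(1, n_passes + 1):
        surv = np.flatnonzero(~total)
        if surv.size < min_survivors:
            raise ValueError(
                f"fewer than {min_survivors} epochs survive rejection"
            )
        stats_p = _epoch_statistics(data[surv])
        pass_mask = np.zeros(n, dtype=bool)
        for name, thr in thresholds.items():
            z = _robust_z_columns(stats_p[name])
            flag = np.zeros(n, dtype=bool)
            flag[surv] = np.max(z, axis=1) > thr
            reasons[f"{name}_pass{p}"] = flag
            pass_mask |= flag
        total |= pass_mask
    if (~total).sum() < min_survivors:
        raise ValueError(f"fewer than {min_survivors} epochs survive rejection")
    return total, reasons


def apply_rejection(delta_epochs: Epochs, mask: np.ndarray, reasons=None) -> Epochs:
    """Attach a rejection mask (computed on broadband epochs) to the
    delta-band epochs."""
    out = Epochs(
        data=delta_epochs.data,
        times=delta_epochs.times,
        fs=delta_epochs.fs,
        alignment=delta_epochs.alignment,
        band=delta_epochs.band,
        channel_names=list(delta_epochs.channel_names),
        reject_mask=np.asarray(mask, dtype=bool),
        reject_reasons={} if reasons is None else dict(reasons),
    )
    return out
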