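"""Core data containers shared across all pipeline stages.

Times are always stored in seconds. Channel-major arrays
(``channels x samples``) are used for continuous data; epoched data is
``trials x channels x time``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

EEG = "eeg"
EOG = "eog"
CURSOR = "cursor"

CONDITIONS = ("exe", "obs")
DIRECTIONS = ("right", "up", "left", "down")

#: movement direction -> angle in radians (right = 0, counter-clockwise)
DIRECTION_ANGLES = {
    "right": 0.0,
    "up": np.pi / 2,
    "left": np.pi,
    "down": 3 * np.pi / 2,
}


@dataclass
class Recording:
    """A continuous multichannel signal block.

    Parameters
    ----------
    data
        ``channels x samples`` array; EEG/EOG in microvolt, cursor distance
        in normalized screen units (0 = origin, 1 = target circle).
    fs
        Sampling rate in Hz.
    channel_names, channel_types
        Per-channel metadata; types are ``eeg``, ``eog`` or ``cursor``.
    events
        List of ``(label, time_s)`` tuples with times inside the recording.
    channel_positions
        Optional ``channels x 3`` electrode coordinates (meters, head
        frame); rows may be NaN for non-EEG channels.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    channel_types: list[str]
    events: list[tuple[str, float]] = field(default_factory=list)
    channel_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        n = self.data.shape[0]
        if len(self.channel_names) != n or len(self.channel_types) != n:
            raise ValueError("channel metadata does not match data")
        dur = self.duration
        for label, t in self.events:
            if not (-1e-9 <= t <= dur + 1e-9):
                raise ValueError(
                    f"event {label!r} at {t:.3f}s outside recording "
                    f"of duration {dur:.3f}s"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def picks(self, ctype: str) -> np.ndarray:
        """Indices of channels with the given type."""
        return np.array(
            [i for i, t in enumerate(self.channel_types) if t == ctype],
            dtype=int,
        )

    def get_channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            channel_types=list(self.channel_types),
            events=list(self.events),
            channel_positions=None
            if self.channel_positions is None
            else self.channel_positions.copy(),
        )


@dataclass
class Epochs:
    """Trials x channels x time array tied to one alignment and band.

    ``reject_mask`` marks trials to drop (``True`` = rejected);
    ``reject_reasons`` keeps one boolean mask per rejection criterion so the
    provenance of every rejected trial stays inspectable.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    alignment: str
    band: str
    channel_names: list[str]
    reject_mask: np.ndarray | None = None
    reject_reasons: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x time")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time vector does not match data")
        dt = np.diff(self.times)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("time vector must be uniform and increasing")
        if self.reject_mask is not None and len(self.reject_mask) != len(
            self.data
        ):
            raise ValueError("reject mask length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def good(self) -> np.ndarray:
        """Boolean mask of surviving trials."""
        if self.reject_mask is None:
            return np.ones(self.n_trials, dtype=bool)
        return ~np.asarray(self.reject_mask, dtype=bool)

    def subset(self, idx: Sequence[int] | np.ndarray) -> "Epochs":
        idx = np.asarray(idx)
        return Epochs(
            data=self.data[idx],
            times=self.times.copy(),
            fs=self.fs,
            alignment=self.alignment,
            band=self.band,
            channel_names=list(self.channel_names),
            reject_mask=None
            if self.reject_mask is None
            else np.asarray(self.reject_mask)[idx],
        )


#: canonical ROI names along the dorsal reaching system, both hemispheres
ROI_NAMES = (
    "PO-L",
    "PO-R",
    "SPL-L",
    "SPL-R",
    "PM-L",
    "PM-R",
    "SM1-L",
    "SM1-R",
)


@dataclass
class Leadfield:
    """Linear forward map from dipole moments to scalp potentials.

    ``gain`` has shape ``channels x (3 * n_voxels)`` in microvolt per nAm;
    the three columns of voxel ``v`` are the x/y/z moment components.
    """

    gain: np.ndarray
    voxel_positions: np.ndarray
    channel_positions: np.ndarray
    roi_labels: np.ndarray
    radius: float = 0.095

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain matrix contains non-finite values")
        if np.any(np.all(self.gain == 0, axis=0)):
            raise ValueError("gain matrix has an all-zero column")
        if self.gain.shape[1] != 3 * self.n_voxels:
            raise ValueError("gain must have 3 columns per voxel")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.voxel_positions.shape[0]

    def roi_voxels(self, roi: str) -> np.ndarray:
        return np.flatnonzero(self.roi_labels == roi)

    def gain3(self) -> np.ndarray:
        """Gain reshaped to ``channels x voxels x 3``."""
        return self.gain.reshape(self.n_channels, self.n_voxels, 3)
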