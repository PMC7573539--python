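"""HDF5 dataset container and BIDS-style events.tsv readers/writers."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import Leadfield, Recording
from .simulate import Experiment, SimulationConfig

SCHEMA_VERSION = "deltareach-1"


class SchemaError(IOError):
    """Raised when a container does not match the expected schema."""


def _write_recording(grp: h5py.Group, rec: Recording) -> None:
    grp.create_dataset("data", data=rec.data)
    grp.attrs["fs"] = rec.fs
    grp.create_dataset(
        "channel_names", data=np.array(rec.channel_names, dtype="S")
    )
    grp.create_dataset(
        "channel_types", data=np.array(rec.channel_types, dtype="S")
    )
    if rec.channel_positions is not None:
        grp.create_dataset("channel_positions", data=rec.channel_positions)
    ev = grp.create_group("events")
    ev.create_dataset(
        "label", data=np.array([e[0] for e in rec.events], dtype="S")
    )
    ev.create_dataset("time", data=np.array([e[1] for e in rec.events]))


def _read_recording(grp: h5py.Group) -> Recording:
    events = [
        (lbl.decode(), float(t))
        for lbl, t in zip(grp["events/label"][()], grp["events/time"][()])
    ]
    pos = grp["channel_positions"][()] if "channel_positions" in grp else None
    return Recording(
        data=grp["data"][()],
        fs=float(grp.attrs["fs"]),
        channel_names=[n.decode() for n in grp["channel_names"][()]],
        channel_types=[t.decode() for t in grp["channel_types"][()]],
        events=events,
        channel_positions=pos,
    )


def save_experiment(path: str | Path, exp: Experiment) -> None:
    """Write a synthetic subject to one HDF5 container (plus ground truth)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        # split the combined EEG+EOG block into /eeg and /eog groups
        eeg_idx = exp.eeg.picks("eeg")
        eog_idx = exp.eeg.picks("eog")
        for name, idx in (("eeg", eeg_idx), ("eog", eog_idx)):
            sub = Recording(
                data=exp.eeg.data[idx],
                fs=exp.eeg.fs,
                channel_names=[exp.eeg.channel_names[i] for i in idx],
                channel_types=[exp.eeg.channel_types[i] for i in idx],
                events=exp.eeg.events if name == "eeg" else [],
                channel_positions=None
                if exp.eeg.channel_positions is None
                else exp.eeg.channel_positions[idx],
            )
            _write_recording(f.create_group(name), sub)
        _write_recording(f.create_group("cursor"), exp.cursor)
        _write_recording(f.create_group("calibration"), exp.calibration)

        truth = f.create_group("truth")
        for col in exp.trials.columns:
            vals = exp.trials[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            truth.create_dataset(col, data=vals)

        lf = f.create_group("leadfield")
        lf.create_dataset("gain", data=exp.leadfield.gain)
        lf.create_dataset("voxel_positions", data=exp.leadfield.voxel_positions)
        lf.create_dataset(
            "channel_positions", data=exp.leadfield.channel_positions
        )
        lf.create_dataset(
            "roi_labels", data=exp.leadfield.roi_labels.astype("S")
        )
        lf.attrs["radius"] = exp.leadfield.radius

        cfgs = f.create_group("config")
        for k, v in exp.config.to_dict().items():
            if v is not None:
                cfgs.attrs[k] = v


def load_experiment(path: str | Path) -> Experiment:
    try:
        f = h5py.File(path, "r")
    except OSError as err:
        raise SchemaError(f"not a readable HDF5 container: {path}") from err
    with f:
        if f.attrs.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(
                f"schema mismatch: expected {SCHEMA_VERSION!r}, "
                f"found {f.attrs.get('schema_version')!r}"
            )
        eeg = _read_recording(f["eeg"])
        eog = _read_recording(f["eog"])
        pos = None
        if eeg.channel_positions is not None:
            pos = np.vstack([eeg.channel_positions, np.full((eog.n_channels, 3), np.nan)])
        combined = Recording(
            data=np.vstack([eeg.data, eog.data]),
            fs=eeg.fs,
            channel_names=eeg.channel_names + eog.channel_names,
            channel_types=eeg.channel_types + eog.channel_types,
            events=eeg.events,
            channel_positions=pos,
        )
        cursor = _read_recording(f["cursor"])
        calib = _read_recording(f["calibration"])
        cols = {}
        for col in f["truth"]:
            vals = f["truth"][col][()]
            if vals.dtype.kind == "S":
                vals = np.char.decode(vals.astype("S"))
            cols[col] = vals
        trials = pd.DataFrame(cols)
        lf = Leadfield(
            gain=f["leadfield/gain"][()],
            voxel_positions=f["leadfield/voxel_positions"][()],
            channel_positions=f["leadfield/channel_positions"][()],
            roi_labels=np.char.decode(f["leadfield/roi_labels"][()].astype("S")),
            radius=float(f["leadfield"].attrs["radius"]),
        )
        cfg = SimulationConfig(**{k: v for k, v in f["config"].attrs.items()})
    return Experiment(
        eeg=combined,
        cursor=cursor,
        trials=trials,
        calibration=calib,
        leadfield=lf,
        config=cfg,
    )


def write_events_tsv(path: str | Path, trials: pd.DataFrame) -> None:
    """BIDS-EEG-style events table: onset / duration / trial_type plus the
    detected behavioral events and rejection flags when available."""
    rows = []
    for _, tr in trials.iterrows():
        rows.append(
            {
                "onset": tr["t_trial_start"],
                "duration": 0.0,
                "trial_type": "trial_start",
                "trial_id": tr["trial_id"],
            }
        )
        rows.append(
            {
                "onset": tr["t_condition_cue"],
                "duration": 0.0,
                "trial_type": f"condition_cue/{tr['condition']}",
                "trial_id": tr["trial_id"],
            }
        )
        rows.append(
            {
                "onset": tr["t_direction_cue"],
                "duration": 0.0,
                "trial_type": f"direction_cue/{tr['direction']}",
                "trial_id": tr["trial_id"],
            }
        )
        if np.isfinite(tr.get("detected_onset", np.nan)):
            rows.append(
                {
                    "onset": tr["detected_onset"],
                    "duration": tr.get("duration", 0.0),
                    "trial_type": "cursor_movement",
                    "trial_id": tr["trial_id"],
                    "outlier": bool(tr.get("outlier", False)),
                    "bad_epoch": bool(tr.get("bad_epoch", False)),
                    "criterion": tr.get("bad_epoch_criterion", ""),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.6f")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])
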