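"""Readers and writers: the internal HDF5 epochs container, EEGLAB .set
epoch files (via MNE), and small JSON artifacts for the component space."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .latent import ComponentSpace
from .prep import EpochedDataset, RecordingMeta

_TRIAL_COLS = ("condition", "rt_ms", "responded", "cue_ms", "stimulus_ms",
               "response_ms")


def save_epochs(group: h5py.Group, ds: EpochedDataset) -> None:
    """Write one EpochedDataset into an open HDF5 group."""
    group.create_dataset("data", data=ds.data.astype(np.float32),
                         compression="gzip", compression_opts=1)
    group.create_dataset("time_ms", data=ds.times_ms)
    tr = group.create_group("trials")
    for col in _TRIAL_COLS:
        if col not in ds.trials:
            continue
        v = ds.trials[col].to_numpy()
        if v.dtype == object or v.dtype.kind in "US":
            v = np.asarray(v, dtype="S")
        tr.create_dataset(col, data=v)
    rec = group.create_group("recording")
    rec.attrs.update({
        "recording_id": ds.recording.recording_id,
        "participant": ds.recording.participant,
        "age": ds.recording.age,
        "sex": ds.recording.sex,
        "wave": ds.recording.wave,
    })
    group.attrs.update({"fs": ds.fs, "lock": ds.lock, "start_ms": ds.start_ms})


def load_epochs(group: h5py.Group) -> EpochedDataset:
    trials = {}
    for col, v in group["trials"].items():
        arr = v[()]
        if arr.dtype.kind == "S":
            arr = arr.astype(str)
        trials[col] = arr
    rec = group["recording"].attrs
    meta = RecordingMeta(
        recording_id=str(rec["recording_id"]),
        participant=str(rec["participant"]),
        age=float(rec["age"]),
        sex=str(rec["sex"]),
        wave=int(rec["wave"]),
    )
    return EpochedDataset(
        data=group["data"][()].astype(np.float64),
        fs=float(group.attrs["fs"]),
        lock=str(group.attrs["lock"]),
        start_ms=float(group.attrs["start_ms"]),
        trials=pd.DataFrame(trials),
        recording=meta,
    )


def save_cohort(path: str | Path, sessions: list[EpochedDataset]) -> None:
    """One HDF5 file holding every session under /sessions/<recording_id>."""
    with h5py.File(path, "w") as f:
        root = f.create_group("sessions")
        for ds in sessions:
            save_epochs(root.create_group(ds.recording.recording_id), ds)


def load_cohort(path: str | Path) -> list[EpochedDataset]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f["sessions"]):
            out.append(load_epochs(f["sessions"][key]))
    return out


def save_component_space(path: str | Path, space: ComponentSpace) -> None:
    payload = {
        "loadings": space.loadings.tolist(),
        "explained_fraction": space.explained_fraction.tolist(),
        "fit_provenance": space.fit_provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_component_space(path: str | Path) -> ComponentSpace:
    payload = json.loads(Path(path).read_text())
    return ComponentSpace(
        loadings=np.asarray(payload["loadings"]),
        explained_fraction=np.asarray(payload["explained_fraction"]),
        fit_provenance=payload.get("fit_provenance", {}),
    )


def read_eeglab_epochs(path: str | Path, recording: RecordingMeta,
                       trials: pd.DataFrame | None = None) -> EpochedDataset:
    """Read an EEGLAB .set epochs file (with companion .fdt) through MNE.

    EEGLAB files do not carry this analysis's per-trial task metadata
    (condition, RT, event latencies); supply it as a ``trials`` table or it
    is filled with placeholders (all trials responded, unknown condition
    mapped to congruent_correct).
    """
    import mne

    epochs = mne.io.read_epochs_eeglab(str(path), verbose="error")
    data = epochs.get_data(copy=True) * 1e6  # Volts -> microvolts
    n = data.shape[0]
    if trials is None:
        trials = pd.DataFrame({
            "condition": ["congruent_correct"] * n,
            "rt_ms": [np.nan] * n,
            "responded": [True] * n,
            "cue_ms": [0.0] * n,
            "stimulus_ms": [np.nan] * n,
            "response_ms": [np.nan] * n,
        })
        trials["rt_ms"] = 1.0  # placeholder satisfying rt > 0 for responded
    return EpochedDataset(
        data=data,
        fs=float(epochs.info["sfreq"]),
        lock="trial",
        start_ms=float(epochs.times[0] * 1000.0),
        trials=trials,
        recording=recording,
    )
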