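"""HDF5 epoch container, events TSV and ground-truth sidecar JSON.

Container layout: ``/data`` (trials x channels x samples, float32),
``/labels`` (int64), attributes ``sfreq``, ``t0``, ``band``, ``space`` and
optionally ``channel_names``.  Round-trips are bit-exact for float32 data
and for all metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EMGEpochs, Epochs, GroundTruth

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_emg",
    "load_emg",
    "save_events_tsv",
    "save_ground_truth",
    "load_ground_truth",
]


def save_epochs(path, epochs: Epochs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32, copy=False))
        f.create_dataset("labels", data=epochs.labels.astype(np.int64))
        f.attrs["sfreq"] = float(epochs.sfreq)
        f.attrs["t0"] = float(epochs.t0)
        f.attrs["band"] = epochs.band
        f.attrs["space"] = epochs.space
        if epochs.channel_names is not None:
            f.attrs["channel_names"] = [str(c) for c in epochs.channel_names]


def load_epochs(path) -> Epochs:
    with h5py.File(path, "r") as f:
        names = f.attrs.get("channel_names")
        return Epochs(
            data=f["data"][()],
            labels=f["labels"][()],
            sfreq=float(f.attrs["sfreq"]),
            t0=float(f.attrs["t0"]),
            band=str(f.attrs["band"]),
            space=str(f.attrs["space"]),
            channel_names=None if names is None else [str(c) for c in names],
        )


def save_emg(path, emg: EMGEpochs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=emg.data.astype(np.float32, copy=False))
        f.create_dataset("labels", data=emg.labels.astype(np.int64))
        f.attrs["sfreq"] = float(emg.sfreq)
        f.attrs["cue_sample"] = int(emg.cue_sample)
        f.attrs["space"] = "emg"


def load_emg(path) -> EMGEpochs:
    with h5py.File(path, "r") as f:
        return EMGEpochs(
            data=f["data"][()],
            labels=f["labels"][()],
            sfreq=float(f.attrs["sfreq"]),
            cue_sample=int(f.attrs["cue_sample"]),
        )


def save_events_tsv(path, labels: np.ndarray, onsets_s: np.ndarray | None = None) -> None:
    df = pd.DataFrame({"trial": np.arange(len(labels)), "label": labels})
    if onsets_s is not None:
        df["onset_s"] = onsets_s
    df.to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_ground_truth(path, truth: GroundTruth) -> None:
    payload = {
        "task_labels": truth.task_labels.tolist(),
        "active_vertex_sets": {
            f"{k[0]}|{k[1]}": np.asarray(v).tolist()
            for k, v in truth.active_vertex_sets.items()
        },
        "emg_onsets": _jsonable(truth.emg_onsets),
        "emg_offsets": _jsonable(truth.emg_offsets),
    }
    Path(path).write_text(json.dumps(payload))


def load_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())

    def _key(s: str):
        a, b = s.split("|")
        try:
            a = int(a)
        except ValueError:
            pass
        return (a, b)

    return GroundTruth(
        task_labels=np.asarray(payload["task_labels"], dtype=np.int64),
        active_vertex_sets={
            _key(k): np.asarray(v, dtype=int)
            for k, v in payload["active_vertex_sets"].items()
        },
        emg_onsets=(
            None
            if payload["emg_onsets"] is None
            else np.asarray(payload["emg_onsets"], dtype=int)
        ),
        emg_offsets=(
            None
            if payload["emg_offsets"] is None
            else np.asarray(payload["emg_offsets"], dtype=int)
        ),
    )
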