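"""HDF5 / CSV / YAML serialization for recordings, epochs and results."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .data import EpochSet, HemodynamicRecording


def save_recording(path, rec: HemodynamicRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal, track_times=False)
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["subject_id"] = rec.subject_id
        f.create_dataset(
            "channel_pair", data=[p for p, _ in rec.channel_roles],
            dtype="i8", track_times=False,
        )
        f.create_dataset(
            "channel_species",
            data=[s.encode() for _, s in rec.channel_roles],
            track_times=False,
        )
        ann = np.array(rec.trial_annotations, dtype=np.int64).reshape(-1, 2)
        f.create_dataset("trial_annotations", data=ann, track_times=False)


def load_recording(path) -> HemodynamicRecording:
    with h5py.File(path, "r") as f:
        roles = [
            (int(p), s.decode())
            for p, s in zip(f["channel_pair"][()], f["channel_species"][()])
        ]
        ann = [(int(o), int(l)) for o, l in f["trial_annotations"][()]]
        return HemodynamicRecording(
            signal=f["signal"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            channel_roles=roles,
            trial_annotations=ann,
            subject_id=int(f.attrs["subject_id"]),
        )


def save_epoch_set(path, ep: EpochSet, config_hash: str | None = None) -> None:
    """EpochSet to HDF5 with labels, subject ids and provenance."""
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=ep.epochs, track_times=False)
        f.create_dataset("labels", data=ep.labels, track_times=False)
        f.create_dataset("subject_ids", data=ep.subject_ids, track_times=False)
        f.attrs["sampling_rate"] = ep.sampling_rate
        f.attrs["epoch_length_s"] = ep.epoch_length_s
        if config_hash:
            f.attrs["config_hash"] = config_hash
        f.create_dataset(
            "channel_pair", data=[p for p, _ in ep.channel_roles],
            dtype="i8", track_times=False,
        )
        f.create_dataset(
            "channel_species",
            data=[s.encode() for _, s in ep.channel_roles],
            track_times=False,
        )
        if ep.trial_onsets is not None:
            f.create_dataset("trial_onsets", data=ep.trial_onsets, track_times=False)
        if ep.trial_ids is not None:
            f.create_dataset("trial_ids", data=ep.trial_ids, track_times=False)


def load_epoch_set(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        roles = [
            (int(p), s.decode())
            for p, s in zip(f["channel_pair"][()], f["channel_species"][()])
        ]
        return EpochSet(
            epochs=f["epochs"][()],
            labels=f["labels"][()],
            subject_ids=f["subject_ids"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            epoch_length_s=float(f.attrs["epoch_length_s"]),
            channel_roles=roles,
            trial_onsets=f["trial_onsets"][()] if "trial_onsets" in f else None,
            trial_ids=f["trial_ids"][()] if "trial_ids" in f else None,
        )


def write_feature_table(path, pair_feats: np.ndarray, efficiency: np.ndarray,
                        labels: np.ndarray, subject_ids: np.ndarray) -> None:
    """Tidy CSV: one row per (epoch, pair) with s, Sd, RFSMD; plus per-epoch e."""
    n, cp, _ = pair_feats.shape
    rows = {
        "epoch_id": np.repeat(np.arange(n), cp),
        "subject": np.repeat(subject_ids, cp),
        "label": np.repeat(labels, cp),
        "pair_id": np.tile(np.arange(cp), n),
        "strength": pair_feats[:, :, 0].ravel(),
        "density": pair_feats[:, :, 1].ravel(),
        "rfsmd": pair_feats[:, :, 2].ravel(),
        "global_efficiency": np.repeat(efficiency, cp),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_config(path, config: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
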