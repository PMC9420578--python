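"""Readers/writers: delimited-text recordings with JSON sidecars, epoch sets,
feature CSVs, and (optionally, via mne) EDF input."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .features import FeatureMatrix
from .synthetic import EEGRecording


def write_recording_txt(rec: EEGRecording, path) -> Path:
    """Samples-by-channels TSV with a header row; sidecar ``<path>.json``
    carries fs, subject and condition."""
    path = Path(path)
    pd.DataFrame(rec.data.T, columns=rec.channel_labels).to_csv(
        path, sep="\t", index=False, float_format="%.6f")
    sidecar = {"fs": rec.fs, "subject_id": rec.subject_id,
               "condition_id": rec.condition_id,
               "channel_labels": list(rec.channel_labels)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording_txt(path) -> EEGRecording:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(Path(str(path) + ".json").read_text())
    return EEGRecording(data=df.to_numpy().T, fs=float(meta["fs"]),
                        channel_labels=meta["channel_labels"],
                        subject_id=meta["subject_id"],
                        condition_id=int(meta["condition_id"]))


def read_edf(path) -> EEGRecording:
    """Read an EDF recording (requires the optional ``mne`` dependency).

    Subject and condition are taken from the sidecar ``<path>.json`` when
    present, else left as placeholders.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF reading requires mne (pip install mne)") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]),
                        channel_labels=list(raw.ch_names),
                        subject_id=meta.get("subject_id", Path(path).stem),
                        condition_id=int(meta.get("condition_id", -1)))


def write_recordings(recs, out_dir) -> list:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recs:
        name = f"{rec.subject_id}_cond{rec.condition_id}.tsv"
        paths.append(write_recording_txt(rec, out / name))
    return paths


def read_recordings(in_dir) -> list:
    paths = sorted(Path(in_dir).glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no .tsv recordings under {in_dir}")
    return [read_recording_txt(p) for p in paths]


def write_epochs(epochs: EpochSet, out_dir) -> Path:
    """One flattened (channel-major) row per epoch plus a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n, c, s = epochs.epochs.shape
    np.savetxt(out / "epochs.tsv", epochs.epochs.reshape(n, c * s),
               delimiter="\t", fmt="%.6f")
    pd.DataFrame({
        "epoch": np.arange(n),
        "subject": epochs.subject_ids,
        "condition": epochs.labels,
    }).to_csv(out / "manifest.csv", index=False)
    meta = {"fs": epochs.fs, "n_channels": c, "epoch_samples": s}
    (out / "meta.json").write_text(json.dumps(meta))
    return out


def read_epochs(in_dir) -> EpochSet:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    flat = np.loadtxt(in_dir / "epochs.tsv", delimiter="\t", ndmin=2)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    c, s = int(meta["n_channels"]), int(meta["epoch_samples"])
    return EpochSet(epochs=flat.reshape(-1, c, s),
                    labels=manifest["condition"].to_numpy(int),
                    subject_ids=manifest["subject"].to_numpy(object),
                    fs=float(meta["fs"]))


def write_features_csv(fm: FeatureMatrix, path,
                       train_mask: np.ndarray | None = None) -> Path:
    df = pd.DataFrame(fm.X, columns=fm.column_names)
    df.insert(0, "subject", fm.subject_ids)
    df.insert(1, "condition", fm.y)
    if train_mask is not None:
        df.insert(2, "is_train", np.asarray(train_mask, bool))
    df.to_csv(path, index=False)
    return Path(path)


def read_features_csv(path):
    """Returns ``(FeatureMatrix, train_mask or None)``."""
    df = pd.read_csv(path)
    mask = None
    if "is_train" in df.columns:
        mask = df.pop("is_train").to_numpy(bool)
    subjects = df.pop("subject").to_numpy(object)
    y = df.pop("condition").to_numpy(int)
    fm = FeatureMatrix(X=df.to_numpy(float), y=y, subject_ids=subjects,
                       column_names=list(df.columns))
    return fm, mask
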