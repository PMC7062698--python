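"""HDF5 and TSV containers for recordings, epochs, montages and results."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import CLASS_ORDER, ContinuousRecording, EpochSet, Event, class_index
from .montage import Montage
from .nn import EEGNet, NetConfig, TrainedModel

__all__ = [
    "save_recording",
    "load_recording",
    "save_epochs",
    "load_epochs",
    "save_montage_tsv",
    "load_montage_tsv",
    "save_model",
    "load_model",
]

_EVENT_DTYPE = np.dtype(
    [("onset_sample", "i8"), ("class", "i1"), ("correct", "?"),
     ("rt_ms", "f8")]
)


def _write_montage(group: h5py.Group, montage: Montage) -> None:
    group.create_dataset(
        "names", data=np.array(montage.names, dtype=h5py.string_dtype())
    )
    group.create_dataset("positions", data=montage.positions)


def _read_montage(group: h5py.Group) -> Montage:
    names = tuple(n.decode() if isinstance(n, bytes) else n
                  for n in group["names"][()])
    return Montage(names=names, positions=group["positions"][()])


def save_recording(path: str | Path, rec: ContinuousRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype(np.float32))
        ev = np.array(
            [(e.onset_sample, class_index(e.trial_class), e.correct, e.rt_ms)
             for e in rec.events],
            dtype=_EVENT_DTYPE,
        )
        f.create_dataset("events", data=ev)
        f.attrs["sfreq"] = rec.sfreq
        f.attrs["subject_id"] = rec.subject_id
        _write_montage(f.create_group("montage"), rec.montage)


def load_recording(path: str | Path) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        ev = f["events"][()]
        events = [
            Event(
                onset_sample=int(row["onset_sample"]),
                trial_class=CLASS_ORDER[int(row["class"])],
                correct=bool(row["correct"]),
                rt_ms=float(row["rt_ms"]),
            )
            for row in ev
        ]
        return ContinuousRecording(
            subject_id=str(f.attrs["subject_id"]),
            sfreq=float(f.attrs["sfreq"]),
            data=f["data"][()].astype(np.float64),
            events=events,
            montage=_read_montage(f["montage"]),
        )


def save_epochs(path: str | Path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("time_ms", data=epochs.time_ms)
        if epochs.rt_ms is not None:
            f.create_dataset("rt_ms", data=epochs.rt_ms)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["csd_applied"] = epochs.csd_applied
        _write_montage(f.create_group("montage"), epochs.montage)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            subject_id=str(f.attrs["subject_id"]),
            data=f["data"][()].astype(np.float64),
            time_ms=f["time_ms"][()],
            labels=f["labels"][()],
            montage=_read_montage(f["montage"]),
            sfreq=float(f.attrs["sfreq"]),
            csd_applied=bool(f.attrs["csd_applied"]),
            rt_ms=f["rt_ms"][()] if "rt_ms" in f else None,
        )


def save_montage_tsv(path: str | Path, montage: Montage) -> None:
    pd.DataFrame(
        {
            "name": montage.names,
            "x": montage.positions[:, 0],
            "y": montage.positions[:, 1],
            "z": montage.positions[:, 2],
        }
    ).to_csv(path, sep="\t", index=False)


def load_montage_tsv(path: str | Path) -> Montage:
    df = pd.read_csv(path, sep="\t")
    return Montage(
        names=tuple(df["name"]), positions=df[["x", "y", "z"]].to_numpy()
    )


def save_model(path: str | Path, trained: TrainedModel) -> None:
    """Weights as .npz with a JSON config sidecar and TSV history."""
    path = Path(path)
    model = trained.model
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays.update({f"running_{k}": v for k, v in model.running.items()})
    np.savez(path.with_suffix(".npz"), **arrays)
    cfg = {
        "F1": model.cfg.F1,
        "D": model.cfg.D,
        "temporal_kernel": model.cfg.temporal_kernel,
        "separable_kernel": model.cfg.separable_kernel,
        "pool1": model.cfg.pool1,
        "pool2": model.cfg.pool2,
        "dropout_p": model.cfg.dropout_p,
        "n_classes": model.cfg.n_classes,
        "C": model.C,
        "T": model.T,
        "best_epoch": trained.best_epoch,
    }
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))
    trained.history.to_csv(path.with_suffix(".history.tsv"), sep="\t",
                           index=False)


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    cfg_d = json.loads(path.with_suffix(".json").read_text())
    cfg = NetConfig(
        F1=cfg_d["F1"], D=cfg_d["D"],
        temporal_kernel=cfg_d["temporal_kernel"],
        separable_kernel=cfg_d["separable_kernel"],
        pool1=cfg_d["pool1"], pool2=cfg_d["pool2"],
        dropout_p=cfg_d["dropout_p"], n_classes=cfg_d["n_classes"],
    )
    model = EEGNet(cfg, cfg_d["C"], cfg_d["T"])
    with np.load(path.with_suffix(".npz")) as npz:
        for k in model.params:
            model.params[k] = npz[f"param_{k}"]
        for k in model.running:
            model.running[k] = npz[f"running_{k}"]
    hist_path = path.with_suffix(".history.tsv")
    history = (pd.read_csv(hist_path, sep="\t") if hist_path.exists()
               else pd.DataFrame(columns=["epoch", "train_loss", "val_loss"]))
    return TrainedModel(model=model, history=history,
                        best_epoch=cfg_d["best_epoch"])
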