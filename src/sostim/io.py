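"""File formats exchanged between pipeline stages.

EEG comes in as EDF/BDF (via :mod:`mne`, when installed) or as a plain
channel-matrix file (CSV or float64 binary) with a sidecar JSON header
``{"fs": ..., "channel_names": [...]}``; the hypnogram is a text file
with one stage label per 30-s epoch. Detected events travel as TSV,
labelled co-detection output as TSV plus a centroid CSV, transfer
models and CD stores as HDF5.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cd import ImportedTransferModel, TransferModel
from .detection import EEGRecording, SOEvent
from .montage import Montage
from .regions import RegionSet

EVENT_COLUMNS = ["channel", "t_start", "t_trough", "t_mid", "t_end",
                 "trough_amp", "range_amp", "stage"]


def _as_str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


def read_hypnogram(path) -> list[str]:
    """One stage label per line (Wake/S1/S2/SWS/REM); blanks ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_hypnogram(path, stages: list[str]) -> None:
    Path(path).write_text("\n".join(stages) + "\n")


def read_eeg(path, hypnogram_path=None, header_path=None) -> EEGRecording:
    """Load an EEG recording from EDF/BDF or a matrix file + JSON header."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".edf", ".bdf"):
        import mne  # deferred: EDF support is optional

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        signals = raw.get_data() * 1e6  # V → µV
        fs = float(raw.info["sfreq"])
        names = list(raw.ch_names)
    else:
        header_path = header_path or path.with_suffix(".json")
        header = json.loads(Path(header_path).read_text())
        fs = float(header["fs"])
        names = list(header["channel_names"])
        if suffix == ".csv":
            signals = pd.read_csv(path, header=None).to_numpy(dtype=float)
        else:
            signals = np.fromfile(path, dtype=np.float64).reshape(len(names), -1)
    if hypnogram_path is None:
        raise ValueError("a hypnogram file is required")
    return EEGRecording(signals=signals, fs=fs, channel_names=names,
                        hypnogram=read_hypnogram(hypnogram_path))


def write_eeg_csv(path, rec: EEGRecording, hypnogram_path=None) -> None:
    path = Path(path)
    pd.DataFrame(rec.signals).to_csv(path, header=False, index=False)
    header = {"fs": rec.fs, "channel_names": rec.channel_names}
    path.with_suffix(".json").write_text(json.dumps(header))
    if hypnogram_path is not None:
        write_hypnogram(hypnogram_path, rec.hypnogram)


def write_events_tsv(path, events: list[SOEvent],
                     extra: pd.DataFrame | None = None) -> None:
    df = pd.DataFrame([{k: v for k, v in asdict(e).items() if k != "ref_amp"}
                       for e in events], columns=EVENT_COLUMNS)
    if extra is not None:
        df = pd.concat([df.reset_index(drop=True),
                        extra.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list[SOEvent]:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events TSV missing columns: {sorted(missing)}")
    return [SOEvent(**{c: row[c] for c in EVENT_COLUMNS})
            for _, row in df.iterrows()]


def read_partition_yaml(path) -> tuple[list[str], list[str]]:
    """Frontal/posterior electrode partition for cluster labelling."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "frontal" not in doc or "posterior" not in doc:
        raise ValueError("partition YAML needs 'frontal' and 'posterior' lists")
    return list(doc["frontal"]), list(doc["posterior"])


def write_transfer_h5(path, tm: TransferModel, montages: list[Montage]) -> None:
    """Materialise a transfer model for a montage list as HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["regions"] = [r.encode() for r in tm.regions.names]
        f.attrs["provenance"] = tm.provenance
        keys = [m.key for m in montages]
        vecs = np.stack([tm.vector(m) for m in montages])
        f.create_dataset("montage_keys", data=np.array([k.encode() for k in keys]))
        f.create_dataset("vectors", data=vecs)


def read_transfer_h5(path) -> ImportedTransferModel:
    with h5py.File(path, "r") as f:
        names = tuple(_as_str(r) for r in f.attrs["regions"])
        keys = [_as_str(k) for k in f["montage_keys"][()]]
        vecs = np.asarray(f["vectors"])
    regions = RegionSet(names)
    return ImportedTransferModel(dict(zip(keys, vecs)), regions=regions)
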