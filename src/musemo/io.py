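"""Readers and writers for recordings, segments and feature matrices.

HDF5 layout for recordings: dataset ``eeg`` (channels x samples) with
attrs ``fs`` and ``channels``.  Feature matrices store datasets
``features``, ``labels_valence``, ``labels_arousal``, ``class`` plus
``band_order`` / ``channel_order`` / ``log_base`` attrs.

EDF support: a minimal 16-bit EDF writer (one data record per second,
per-channel physical scaling) plus readers for EDF (via mne, optional
dependency), plain CSV (rows = samples, header = channel labels, sampling
rate in a sidecar or argument) and the HDF5 layout above.
"""

from __future__ import annotations

import datetime as _dt

import h5py
import numpy as np
import pandas as pd

from .core import LabeledSegment, Recording
from .features import DEMatrix

__all__ = [
    "save_recording_h5", "load_recording_h5",
    "save_recording_edf", "load_recording_edf", "load_recording_csv",
    "load_recording_brainvision", "save_features_csv",
    "save_ratings_csv", "load_ratings_csv",
    "save_segments_h5", "load_segments_h5",
    "save_features_h5", "load_features_h5",
]


# ---------------------------------------------------------------------- HDF5

def save_recording_h5(recording: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("eeg", data=recording.data)
        d.attrs["fs"] = float(recording.fs)
        d.attrs["channels"] = [str(c) for c in recording.channel_labels]
        for key, val in recording.meta.items():
            if isinstance(val, (str, int, float)):
                d.attrs[f"meta_{key}"] = val


def load_recording_h5(path) -> Recording:
    with h5py.File(path, "r") as f:
        d = f["eeg"]
        data = d[()]
        fs = float(d.attrs["fs"])
        channels = [c.decode() if isinstance(c, bytes) else str(c)
                    for c in d.attrs["channels"]]
        meta = {k[5:]: (v.item() if hasattr(v, "item") else v)
                for k, v in d.attrs.items() if k.startswith("meta_")}
        meta = {k: (v.decode() if isinstance(v, bytes) else v)
                for k, v in meta.items()}
    return Recording(data=data, fs=fs, channel_labels=channels, meta=meta)


# ----------------------------------------------------------------------- EDF

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def save_recording_edf(recording: Recording, path) -> None:
    """Write a 16-bit EDF file, one 1-s data record per second.

    The trailing partial second (if any) is zero-padded in the last
    record's tail; physical min/max are taken from the data per channel.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / fs))
    data = np.zeros((n_ch, n_records * fs))
    data[:, : recording.n_samples] = recording.data

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = np.where(phys_max - phys_min <= 0, 1.0, phys_max - phys_min)
    dig_min, dig_max = -32768, 32767
    scaled = (data - phys_min[:, None]) / span[:, None]
    digital = np.round(scaled * (dig_max - dig_min) + dig_min).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b""
    header += _edf_field("0", 8)                       # version
    header += _edf_field("X X X X", 80)                # patient id
    header += _edf_field("Startdate X X X X", 80)      # recording id
    header += _edf_field(now.strftime("%d.%m.%y"), 8)
    header += _edf_field(now.strftime("%H.%M.%S"), 8)
    header += _edf_field(256 + 256 * n_ch, 8)          # header bytes
    header += _edf_field("", 44)                       # reserved
    header += _edf_field(n_records, 8)
    header += _edf_field(1, 8)                         # record duration (s)
    header += _edf_field(n_ch, 4)

    labels = [str(c) for c in recording.channel_labels]
    header += b"".join(_edf_field(lb, 16) for lb in labels)
    header += b"".join(_edf_field("EEG", 80) for _ in labels)      # transducer
    header += b"".join(_edf_field("uV", 8) for _ in labels)        # unit
    header += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in phys_min)
    header += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in phys_max)
    header += b"".join(_edf_field(dig_min, 8) for _ in labels)
    header += b"".join(_edf_field(dig_max, 8) for _ in labels)
    header += b"".join(_edf_field("", 80) for _ in labels)         # prefilter
    header += b"".join(_edf_field(fs, 8) for _ in labels)          # samples/rec
    header += b"".join(_edf_field("", 32) for _ in labels)         # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())


def load_recording_edf(path) -> Recording:
    """Read an EDF file via mne (optional dependency)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; recordings are in µV
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names))


def load_recording_brainvision(path) -> Recording:
    """Read a BrainVision (.vhdr) recording via mne (optional dependency)."""
    import mne

    raw = mne.io.read_raw_brainvision(str(path), preload=True, verbose="error")
    return Recording(data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names))


def load_recording_csv(path, fs: float) -> Recording:
    """CSV with one row per sample and one column per channel."""
    df = pd.read_csv(path)
    return Recording(data=df.to_numpy(dtype=np.float64).T, fs=fs,
                     channel_labels=[str(c) for c in df.columns])


# ------------------------------------------------------------------- ratings

def save_ratings_csv(ratings: pd.DataFrame, path) -> None:
    ratings.to_csv(path, index=False,
                   columns=["trial_id", "class", "valence", "arousal"])


def load_ratings_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ------------------------------------------------------------------ segments

def save_segments_h5(segments: list[LabeledSegment], path) -> None:
    if not segments:
        raise ValueError("no segments to save")
    data = np.stack([s.data for s in segments])
    with h5py.File(path, "w") as f:
        d = f.create_dataset("segments", data=data)
        d.attrs["fs"] = float(segments[0].fs)
        f.create_dataset("class",
                         data=np.array([s.class_name for s in segments], dtype="S"))
        f.create_dataset("valence", data=[s.valence_label for s in segments])
        f.create_dataset("arousal", data=[s.arousal_label for s in segments])
        f.create_dataset("trial_id",
                         data=np.array([s.trial_id for s in segments], dtype="S"))
        f.create_dataset("window_index", data=[s.window_index for s in segments])


def load_segments_h5(path) -> list[LabeledSegment]:
    with h5py.File(path, "r") as f:
        data = f["segments"][()]
        fs = float(f["segments"].attrs["fs"])
        cls = [c.decode() for c in f["class"][()]]
        val = f["valence"][()]
        aro = f["arousal"][()]
        tid = [t.decode() for t in f["trial_id"][()]]
        win = f["window_index"][()]
    return [
        LabeledSegment(data=data[i], fs=fs, class_name=cls[i],
                       valence_label=int(val[i]), arousal_label=int(aro[i]),
                       trial_id=tid[i], window_index=int(win[i]))
        for i in range(data.shape[0])
    ]


# ------------------------------------------------------------------ features

def save_features_h5(matrix: DEMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("features", data=matrix.values)
        d.attrs["band_order"] = [str(b) for b in matrix.band_names]
        d.attrs["channel_order"] = [str(c) for c in matrix.channel_labels]
        d.attrs["log_base"] = str(matrix.log_base)
        d.attrs["column_layout"] = "band-major: [b1*ch1..chC, b2*ch1..chC, ...]"
        f.create_dataset("labels_valence",
                         data=matrix.row_meta["valence"].to_numpy(dtype=np.int64))
        f.create_dataset("labels_arousal",
                         data=matrix.row_meta["arousal"].to_numpy(dtype=np.int64))
        f.create_dataset(
            "class",
            data=np.array(matrix.row_meta["class"].astype(str), dtype="S"))
        f.create_dataset(
            "trial_id",
            data=np.array(matrix.row_meta["trial_id"].astype(str), dtype="S"))
        f.create_dataset("window_index",
                         data=matrix.row_meta["window_index"].to_numpy(dtype=np.int64))


def load_features_h5(path) -> DEMatrix:
    with h5py.File(path, "r") as f:
        d = f["features"]
        values = d[()]
        band_names = [b.decode() if isinstance(b, bytes) else str(b)
                      for b in d.attrs["band_order"]]
        channel_labels = [c.decode() if isinstance(c, bytes) else str(c)
                          for c in d.attrs["channel_order"]]
        log_base_raw = d.attrs["log_base"]
        log_base_raw = (log_base_raw.decode()
                        if isinstance(log_base_raw, bytes) else str(log_base_raw))
        log_base = 2 if log_base_raw == "2" else "e"
        meta = pd.DataFrame({
            "class": [c.decode() for c in f["class"][()]],
            "valence": f["labels_valence"][()],
            "arousal": f["labels_arousal"][()],
            "trial_id": [t.decode() for t in f["trial_id"][()]],
            "window_index": f["window_index"][()],
        })
    return DEMatrix(values=values, band_names=band_names,
                    channel_labels=channel_labels, row_meta=meta,
                    log_base=log_base)


def save_features_csv(matrix: DEMatrix, path) -> None:
    """Flat CSV export: one row per segment, DE columns named band:channel,
    label/metadata columns appended."""
    df = pd.DataFrame(matrix.values, columns=matrix.column_names())
    out = pd.concat([matrix.row_meta.reset_index(drop=True), df], axis=1)
    out.to_csv(path, index=False)
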