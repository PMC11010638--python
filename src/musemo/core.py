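"""Core containers shared across the pipeline.

EEG recordings are stored as plain ``channels x samples`` float arrays (µV)
plus a sampling rate, the same in-memory convention mne uses for
``Raw.get_data()``.  Band definitions follow the conventional EEG rhythm
partition used in affective-computing work: theta 4–8 Hz, alpha 8–13 Hz,
beta 13–30 Hz, gamma 30–45 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

#: Conventional EEG rhythm bands (Hz), in canonical order.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Reported per-class 2-s segment counts of the SWU-M music-EEG corpus,
#: retained for bookkeeping checks (the corpus itself is not distributable).
SWU_M_SEGMENT_COUNTS: dict[str, int] = {
    "fear": 2613,
    "happy": 2709,
    "calm": 2384,
    "sad": 2166,
}
SWU_M_TOTAL_SEGMENTS: int = 9872

#: SAM rating statistics (valence mean, valence sd, arousal mean, arousal sd)
#: of the four music stimulus categories, used as generator defaults.
SWU_M_RATING_STATS: dict[str, tuple[float, float, float, float]] = {
    "fear": (3.03, 0.29, 7.12, 0.28),
    "happy": (6.98, 0.30, 7.02, 0.28),
    "calm": (5.85, 0.22, 3.56, 0.27),
    "sad": (3.55, 0.29, 2.86, 0.45),
}

EMOTION_CLASSES: tuple[str, ...] = ("fear", "happy", "calm", "sad")


class BandSet:
    """Ordered mapping band name -> (low_hz, high_hz)."""

    def __init__(self, bands: Mapping[str, tuple[float, float]] | None = None):
        items = dict(bands) if bands is not None else dict(DEFAULT_BANDS)
        for name, (lo, hi) in items.items():
            if not lo < hi:
                raise ValueError(f"band {name!r}: low must be < high, got ({lo}, {hi})")
        self._bands = items

    @property
    def names(self) -> list[str]:
        return list(self._bands)

    def __iter__(self):
        return iter(self._bands.items())

    def __len__(self) -> int:
        return len(self._bands)

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self._bands[name]

    def __contains__(self, name: str) -> bool:
        return name in self._bands

    def __eq__(self, other) -> bool:
        return isinstance(other, BandSet) and self._bands == other._bands

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}=({lo}, {hi})" for k, (lo, hi) in self._bands.items())
        return f"BandSet({inner})"

    def subset(self, names) -> "BandSet":
        unknown = [n for n in names if n not in self._bands]
        if unknown:
            raise KeyError(f"unknown band name(s): {unknown}")
        return BandSet({n: self._bands[n] for n in names})


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is channels x samples in µV."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, fs: float | None = None) -> "Recording":
        return Recording(
            data=data,
            fs=self.fs if fs is None else fs,
            channel_labels=list(self.channel_labels),
            meta=dict(self.meta),
        )


@dataclass
class LabeledSegment:
    """One non-overlapping analysis window with its emotion labels."""

    data: np.ndarray
    fs: float
    class_name: str
    valence_label: int
    arousal_label: int
    trial_id: str
    window_index: int

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("segment data must be 2-D (channels x samples)")
        if self.valence_label not in (0, 1) or self.arousal_label not in (0, 1):
            raise ValueError("labels must be binary")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]
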