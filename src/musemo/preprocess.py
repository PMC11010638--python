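"""Raw EEG -> labeled 2-s band-decomposed segments.

The standard chain is: broadband band-pass (1–45 Hz, 3rd-order Butterworth,
zero-phase), downsample to 128 Hz, baseline correction against the first
2 s of stimulation (mean subtraction, baseline window then dropped),
segmentation into non-overlapping 2-s windows (optionally Hann-tapered with
power renormalization), and rating binarization at the SAM midpoint 5.

Filtering is zero-phase (forward–backward ``sosfiltfilt``), so band power
is not smeared across window boundaries by phase delay.  A rating of
exactly 5 maps to the "high" label 1; the choice is recorded in segment
metadata by :func:`preprocess_dataset`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal

from .core import BandSet, LabeledSegment, Recording

__all__ = [
    "PreprocessConfig",
    "bandpass",
    "resample",
    "baseline_correct",
    "segment",
    "band_decompose",
    "band_decompose_array",
    "binarize_ratings",
    "ica_hook",
    "preprocess_dataset",
]

logger = logging.getLogger(__name__)

RATING_THRESHOLD = 5.0


@dataclass
class PreprocessConfig:
    """End-to-end preprocessing parameters."""

    bandpass_low: float = 1.0
    bandpass_high: float = 45.0
    filter_order: int = 3
    target_fs: float = 128.0
    baseline_seconds: float = 2.0
    window_seconds: float = 2.0
    taper: str = "hann"
    bands: BandSet = field(default_factory=BandSet)
    rating_threshold: float = RATING_THRESHOLD


def _check_band(low: float, high: float, fs: float) -> None:
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for fs={fs} Hz (Nyquist {fs / 2})"
        )


def bandpass(recording: Recording, low_hz: float, high_hz: float,
             order: int = 3) -> Recording:
    """Zero-phase Butterworth band-pass, applied forward and backward."""
    _check_band(low_hz, high_hz, recording.fs)
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=recording.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    return recording.copy_with(filtered)


def resample(recording: Recording, target_fs: float) -> Recording:
    """Polyphase downsampling to ``target_fs`` (upsampling unsupported)."""
    if target_fs > recording.fs:
        raise ValueError("upsampling is not supported")
    if target_fs == recording.fs:
        return recording.copy_with(recording.data.copy())
    frac = Fraction(target_fs / recording.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(recording.data, up, down, axis=1)
    expected = int(round(recording.n_samples * target_fs / recording.fs))
    out = out[:, :expected]
    return recording.copy_with(out, fs=target_fs)


def baseline_correct(recording: Recording, baseline_seconds: float = 2.0) -> Recording:
    """Subtract each channel's mean over the first ``baseline_seconds``,
    then drop the baseline window from the recording."""
    n_base = int(round(baseline_seconds * recording.fs))
    if n_base >= recording.n_samples:
        raise ValueError("recording shorter than the baseline window")
    base_mean = recording.data[:, :n_base].mean(axis=1, keepdims=True)
    corrected = recording.data - base_mean
    return recording.copy_with(corrected[:, n_base:])


def _hann_taper(n: int) -> tuple[np.ndarray, float]:
    w = signal.windows.hann(n, sym=False)
    norm = 1.0 / np.sqrt(np.mean(w**2))
    return w, norm


def segment(recording: Recording, window_seconds: float = 2.0,
            taper: str = "hann") -> list[LabeledSegment]:
    """Cut into non-overlapping windows; trailing partial window dropped.

    With ``taper="hann"`` each window is multiplied by a Hann taper and
    rescaled by 1/sqrt(mean(w^2)) so expected power is preserved.  Labels
    (class, binary valence/arousal, trial id) are copied from
    ``recording.meta``; missing labels default to class ``"unknown"`` and
    labels 0.
    """
    if taper not in ("hann", "none"):
        raise ValueError("taper must be 'hann' or 'none'")
    t = window_seconds * recording.fs
    if abs(t - round(t)) > 1e-9:
        raise ValueError("window_seconds * fs must be an integer")
    t = int(round(t))
    n_windows = recording.n_samples // t
    if n_windows == 0:
        logger.warning("recording shorter than one window; returning no segments")
        return []
    if taper == "hann":
        w, norm = _hann_taper(t)
        w = w * norm
    meta = recording.meta
    segments = []
    for i in range(n_windows):
        chunk = recording.data[:, i * t:(i + 1) * t]
        if taper == "hann":
            chunk = chunk * w[None, :]
        segments.append(
            LabeledSegment(
                data=chunk,
                fs=recording.fs,
                class_name=meta.get("class_name", "unknown"),
                valence_label=int(meta.get("valence_label", 0)),
                arousal_label=int(meta.get("arousal_label", 0)),
                trial_id=str(meta.get("trial_id", "trial")),
                window_index=i,
            )
        )
    return segments


def band_decompose_array(data: np.ndarray, fs: float,
                         bands: BandSet | None = None,
                         order: int = 3) -> dict[str, np.ndarray]:
    """Band-pass ``data`` (…, samples) into each band; preserves shape."""
    bands = bands or BandSet()
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bands:
        _check_band(lo, hi, fs)
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
        out[name] = signal.sosfiltfilt(sos, np.asarray(data, dtype=np.float64),
                                       axis=-1)
    return out


def band_decompose(obj: Recording | LabeledSegment,
                   bands: BandSet | None = None,
                   order: int = 3) -> dict[str, np.ndarray]:
    """Decompose a Recording or LabeledSegment into rhythm bands."""
    return band_decompose_array(obj.data, obj.fs, bands, order)


def binarize_ratings(rating, threshold: float = RATING_THRESHOLD):
    """Map 1–9 SAM ratings to binary labels: ``rating < threshold -> 0``,
    otherwise 1 (a rating exactly at the threshold counts as high)."""
    arr = np.asarray(rating, dtype=np.float64)
    if np.any(arr < 1.0) or np.any(arr > 9.0):
        raise ValueError("ratings must lie in [1, 9]")
    labels = (arr >= threshold).astype(int)
    if np.isscalar(rating) or arr.ndim == 0:
        return int(labels)
    return labels


def ica_hook(recording: Recording) -> Recording:
    """Artifact-removal hook; identity pass-through.

    Ocular/muscular artifact rejection by ICA requires component review by
    an operator and is outside this package; the hook exists so a caller
    can splice a real cleaning step into :func:`preprocess_dataset`.
    """
    return recording


def preprocess_dataset(recordings: Iterable[Recording],
                       ratings: pd.DataFrame,
                       config: PreprocessConfig | None = None,
                       artifact_hook=ica_hook) -> list[LabeledSegment]:
    """Full chain: filter -> downsample -> baseline -> label -> segment."""
    cfg = config or PreprocessConfig()
    table = ratings.set_index("trial_id")
    segments: list[LabeledSegment] = []
    for rec in recordings:
        trial_id = rec.meta.get("trial_id")
        if trial_id not in table.index:
            raise KeyError(f"trial {trial_id!r} missing from the rating table")
        row = table.loc[trial_id]
        rec = artifact_hook(rec)
        rec = bandpass(rec, cfg.bandpass_low, cfg.bandpass_high, cfg.filter_order)
        rec = resample(rec, cfg.target_fs)
        rec = baseline_correct(rec, cfg.baseline_seconds)
        rec.meta.update(
            valence_label=binarize_ratings(float(row["valence"]), cfg.rating_threshold),
            arousal_label=binarize_ratings(float(row["arousal"]), cfg.rating_threshold),
            rating_threshold=cfg.rating_threshold,
            threshold_tie_rule="at-threshold ratings labeled 1 (high)",
        )
        segments.extend(segment(rec, cfg.window_seconds, cfg.taper))
    return segments
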