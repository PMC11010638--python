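"""Synthetic music-evoked EEG with class-dependent band-power signatures.

The generator emulates the statistical structure a music-emotion pipeline
assumes: per-channel 1/f background activity plus narrowband rhythm
components whose amplitudes depend on the stimulated emotion class, and a
per-trial SAM rating table (valence/arousal, 1–9) drawn around the class
means of the stimulus set.  Alpha power carries the class signal by
default, reflecting the alpha-band sensitivity of music stimulation.

Randomness is counter-based: every trial (and every channel/band within a
trial) draws from a ``numpy`` ``SeedSequence`` keyed by
``(seed, class_index, trial_index, ...)``, so identical specs reproduce
datasets byte-for-byte and trials are independent substreams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import (
    DEFAULT_BANDS,
    EMOTION_CLASSES,
    SWU_M_RATING_STATS,
    Recording,
)

__all__ = [
    "ClassProfile",
    "SyntheticDatasetSpec",
    "default_profiles",
    "make_band_signal",
    "make_pink_noise",
    "make_recording",
    "make_dataset",
    "full_scale_spec",
    "small_scale_spec",
]


@dataclass
class ClassProfile:
    """Band-power signature and rating statistics of one emotion class.

    ``band_amplitudes`` are relative RMS amplitudes of narrowband components
    added on top of the 1/f background; ``valence_mean``/``arousal_mean``
    are SAM-scale (1–9) means, ``rating_sd`` their common standard
    deviation.
    """

    class_name: str
    band_amplitudes: dict[str, float]
    valence_mean: float
    arousal_mean: float
    rating_sd: float = 0.3

    def __post_init__(self):
        unknown = set(self.band_amplitudes) - set(DEFAULT_BANDS)
        if unknown:
            raise ValueError(f"unknown band name(s) in profile: {sorted(unknown)}")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band amplitudes must be >= 0")
        for v in (self.valence_mean, self.arousal_mean):
            if not 1.0 <= v <= 9.0:
                raise ValueError("rating means must lie in [1, 9]")
        if self.rating_sd < 0:
            raise ValueError("rating_sd must be >= 0")


@dataclass
class SyntheticDatasetSpec:
    """Dataset-level generation parameters (acquisition geometry + noise)."""

    profiles: list[ClassProfile]
    n_trials_per_class: int = 10
    n_channels: int = 128
    trial_seconds: float = 20.0
    fs: float = 1024.0
    noise_exponent: float = 1.0
    noise_amplitude: float = 1.0
    channel_gain_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not self.profiles:
            raise ValueError("profiles must be non-empty")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        n = self.trial_seconds * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_seconds * fs must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_seconds * self.fs))


def default_profiles(alpha_amplitudes: dict[str, float] | None = None,
                     base_amplitude: float = 1.0) -> list[ClassProfile]:
    """The four stimulus-class profiles used throughout.

    Alpha amplitude doubles from class to class (fear 1, happy 2, calm 4,
    sad 8 by default) so each class is identifiable from alpha power alone
    and every adjacent pair differs by a band-power ratio of 2; the other
    rhythms carry no class information.  Rating means/sds are the stimulus
    statistics of the music set the pipeline targets.
    """
    alpha = alpha_amplitudes or {"fear": 1.0, "happy": 2.0, "calm": 4.0, "sad": 8.0}
    profiles = []
    for name in EMOTION_CLASSES:
        v_mean, v_sd, a_mean, a_sd = SWU_M_RATING_STATS[name]
        profiles.append(
            ClassProfile(
                class_name=name,
                band_amplitudes={
                    "theta": base_amplitude,
                    "alpha": alpha[name],
                    "beta": base_amplitude,
                    "gamma": base_amplitude,
                },
                valence_mean=v_mean,
                arousal_mean=a_mean,
                # common sd: mean of the reported valence/arousal sds
                rating_sd=round((v_sd + a_sd) / 2, 3),
            )
        )
    return profiles


def full_scale_spec(seed: int = 0, n_trials_per_class: int = 10) -> SyntheticDatasetSpec:
    """Acquisition-scale spec: 128 channels at 1024 Hz, 20-s trials."""
    return SyntheticDatasetSpec(
        profiles=default_profiles(),
        n_trials_per_class=n_trials_per_class,
        n_channels=128,
        trial_seconds=20.0,
        fs=1024.0,
        seed=seed,
    )


def small_scale_spec(seed: int = 0, n_trials_per_class: int = 12,
                    n_channels: int = 8, trial_seconds: float = 20.0,
                    fs: float = 128.0) -> SyntheticDatasetSpec:
    """Reduced spec for fast experiments: 8 channels at 128 Hz.

    12 trials/class x 20 s leaves 9 usable 2-s windows per trial after a
    2-s baseline, i.e. 108 segments per class.
    """
    return SyntheticDatasetSpec(
        profiles=default_profiles(),
        n_trials_per_class=n_trials_per_class,
        n_channels=n_channels,
        trial_seconds=trial_seconds,
        fs=fs,
        seed=seed,
    )


def make_band_signal(band: tuple[float, float], amplitude: float,
                     duration_s: float, fs: float, seed) -> np.ndarray:
    """Zero-mean narrowband noise with RMS equal to ``amplitude``.

    White Gaussian noise is zero-phase band-pass filtered (3rd-order
    Butterworth, applied forward and backward) into ``band`` and rescaled
    to the requested RMS, so spectral power concentrates inside the band
    while the waveform still varies from window to window.
    """
    low, high = band
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band ({low}, {high}) must satisfy 0 < low < high < fs/2")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = int(round(duration_s * fs))
    if amplitude == 0:
        return np.zeros(n)
    rng = np.random.Generator(np.random.Philox(seed))
    white = rng.standard_normal(n)
    sos = signal.butter(3, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    x = x - x.mean()
    rms = np.sqrt(np.mean(x**2))
    return x * (amplitude / rms)


def make_pink_noise(duration_s: float, fs: float, exponent: float,
                    amplitude: float, seed) -> np.ndarray:
    """1/f^exponent Gaussian noise via spectral shaping, RMS = amplitude."""
    n = int(round(duration_s * fs))
    if amplitude == 0:
        return np.zeros(n)
    rng = np.random.Generator(np.random.Philox(seed))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n)
    x = x - x.mean()
    rms = np.sqrt(np.mean(x**2))
    return x * (amplitude / rms)


def _class_index(spec: SyntheticDatasetSpec, profile: ClassProfile) -> int:
    for i, p in enumerate(spec.profiles):
        if p.class_name == profile.class_name:
            return i
    raise ValueError(f"profile {profile.class_name!r} not in spec.profiles")


def make_recording(profile: ClassProfile, spec: SyntheticDatasetSpec,
                   trial_index: int) -> Recording:
    """One synthetic trial: per-channel 1/f background + rhythm components.

    Each channel draws independent background and band noise; a small
    multiplicative per-channel gain emulates electrode-contact variation.
    The substream is keyed by (seed, class, trial), so two trial indices of
    the same class never share randomness.
    """
    ci = _class_index(spec, profile)
    ss = np.random.SeedSequence(spec.seed, spawn_key=(ci, trial_index))
    # one child per channel for signals, one extra for gains
    children = ss.spawn(spec.n_channels + 1)
    gain_rng = np.random.Generator(np.random.Philox(children[-1]))
    gains = 1.0 + spec.channel_gain_sd * gain_rng.standard_normal(spec.n_channels)
    gains = np.clip(gains, 0.5, 1.5)

    band_items = [(name, DEFAULT_BANDS[name]) for name in DEFAULT_BANDS
                  if name in profile.band_amplitudes]
    data = np.empty((spec.n_channels, spec.n_samples))
    for ch in range(spec.n_channels):
        ch_ss = children[ch]
        streams = ch_ss.spawn(len(band_items) + 1)
        x = make_pink_noise(spec.trial_seconds, spec.fs, spec.noise_exponent,
                            spec.noise_amplitude, streams[0])
        for k, (name, band) in enumerate(band_items):
            amp = profile.band_amplitudes[name]
            if amp > 0:
                x = x + make_band_signal(band, amp, spec.trial_seconds,
                                         spec.fs, streams[k + 1])
        data[ch] = gains[ch] * x

    trial_id = f"{profile.class_name}_{trial_index:03d}"
    return Recording(
        data=data,
        fs=spec.fs,
        meta={
            "class_name": profile.class_name,
            "trial_index": trial_index,
            "trial_id": trial_id,
        },
    )


def make_dataset(spec: SyntheticDatasetSpec) -> tuple[list[Recording], pd.DataFrame]:
    """Generate all trials plus the per-trial SAM rating table.

    Ratings are drawn from Normal(mean, rating_sd) per dimension and
    clipped to the 1–9 SAM scale.  Returns ``(recordings, ratings)`` where
    ratings has columns ``trial_id, class, valence, arousal``.
    """
    recordings: list[Recording] = []
    rows = []
    for ci, profile in enumerate(spec.profiles):
        for ti in range(spec.n_trials_per_class):
            rec = make_recording(profile, spec, ti)
            recordings.append(rec)
            r_ss = np.random.SeedSequence(spec.seed, spawn_key=(ci, ti, 1))
            rng = np.random.Generator(np.random.Philox(r_ss))
            valence = profile.valence_mean + profile.rating_sd * rng.standard_normal()
            arousal = profile.arousal_mean + profile.rating_sd * rng.standard_normal()
            rows.append(
                {
                    "trial_id": rec.meta["trial_id"],
                    "class": profile.class_name,
                    "valence": float(np.clip(valence, 1.0, 9.0)),
                    "arousal": float(np.clip(arousal, 1.0, 9.0)),
                }
            )
    ratings = pd.DataFrame(rows, columns=["trial_id", "class", "valence", "arousal"])
    return recordings, ratings
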