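"""Differential-entropy (DE) features per channel per rhythm band.

For a Gaussian signal with variance σ², the differential entropy has the
closed form h = ½ log(2πeσ²).  Band-passed EEG windows are treated as
zero-mean Gaussian, so the per-window, per-channel, per-band DE is the
closed form evaluated at the unbiased sample variance.  A symmetric
two-Gaussian mixture density (mean ±μ, sd σ) is kept as a numerical
quadrature oracle: its entropy exceeds the Gaussian closed form by a term
L(μ/σ) that grows from 0 to ln 2 as the modes separate, and it reduces
exactly to the Gaussian case at μ = 0.

Feature matrices are band-major: columns are ordered
[band₁·ch₁ … band₁·ch_C, band₂·ch₁ …], with the ordering recorded in the
container and its HDF5 serialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate

from .core import BandSet, LabeledSegment
from .preprocess import band_decompose_array

__all__ = [
    "DEMatrix",
    "GaussianParams",
    "gaussian_de",
    "mixture_de_numeric",
    "mixture_L",
    "segment_de",
    "build_feature_matrix",
    "select_bands",
]

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-10


def _log_conv(log_base) -> float:
    if log_base == 2:
        return np.log(2.0)
    if log_base in ("e", np.e):
        return 1.0
    raise ValueError("log_base must be 2 or 'e'")


def gaussian_de(sigma2: float, log_base=2) -> float:
    """Closed-form DE of N(·, σ²): ½ log(2πeσ²) in the chosen base."""
    sigma2 = float(sigma2)
    if sigma2 <= 0:
        raise ValueError("variance must be positive (degenerate signal)")
    return 0.5 * np.log(2.0 * np.pi * np.e * sigma2) / _log_conv(log_base)


@dataclass(frozen=True)
class GaussianParams:
    """Location/scale pair for the entropy oracles (sigma > 0)."""

    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _mixture_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    # symmetric two-Gaussian mixture written via cosh
    return (
        1.0 / (np.sqrt(2.0 * np.pi) * sigma)
        * np.exp(-(x**2 + mu**2) / (2.0 * sigma**2))
        * np.cosh(mu * x / sigma**2)
    )


def mixture_de_numeric(mu, sigma: float | None = None, log_base=2) -> float:
    """DE of the symmetric two-Gaussian mixture by adaptive quadrature.

    Serves as the independent oracle for the Gaussian closed form (μ=0)
    and for the separation term L(μ/σ) = h_mixture − ½log(2πeσ²).
    Accepts either ``(mu, sigma)`` or a single :class:`GaussianParams`.
    """
    if isinstance(mu, GaussianParams):
        mu, sigma = mu.mu, mu.sigma
    if sigma is None or sigma <= 0:
        raise ValueError("sigma must be positive")
    mu = abs(float(mu))
    span = mu + 40.0 * sigma

    def integrand(x):
        p = _mixture_pdf(np.asarray(x), mu, sigma)
        return np.where(p > 0, -p * np.log(np.maximum(p, 1e-300)), 0.0)

    val, err = integrate.quad(integrand, -span, span, limit=400,
                              points=[-mu, 0.0, mu])
    if not np.isfinite(val) or err > 1e-6 * max(1.0, abs(val)):
        raise ArithmeticError(
            f"quadrature did not converge (value={val}, abserr={err})"
        )
    return val / _log_conv(log_base)


def mixture_L(mu_over_sigma: float, log_base="e") -> float:
    """Separation term L(μ/σ): 0 at μ=0, → ln 2 (1 bit) as μ/σ → ∞."""
    h_mix = mixture_de_numeric(mu_over_sigma, 1.0, log_base)
    return h_mix - gaussian_de(1.0, log_base)


@dataclass
class DEMatrix:
    """N × (C·B) DE feature matrix with explicit band/channel ordering."""

    values: np.ndarray
    band_names: list[str]
    channel_labels: list[str]
    row_meta: pd.DataFrame
    log_base: object = 2

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = len(self.band_names) * len(self.channel_labels)
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ValueError(
                f"values must be N x {expected} (bands x channels), "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DE values must be finite")
        if len(self.row_meta) != self.values.shape[0]:
            raise ValueError("row_meta length must match row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def column_names(self) -> list[str]:
        return [f"{b}:{c}" for b in self.band_names for c in self.channel_labels]

    def band_slice(self, band: str) -> slice:
        i = self.band_names.index(band)
        c = self.n_channels
        return slice(i * c, (i + 1) * c)


def segment_de(banded: dict[str, np.ndarray], log_base=2,
               band_order: list[str] | None = None) -> np.ndarray:
    """Per-channel, per-band DE of one segment; band-major vector of
    length C·B.  Variances below the floor (1e-10) are clipped up with a
    warning — that only happens on degenerate constant inputs."""
    order = band_order or list(banded)
    chunks = []
    for name in order:
        x = np.asarray(banded[name], dtype=np.float64)
        if x.ndim != 2 or x.shape[1] < 2:
            raise ValueError("each band signal must be channels x T with T >= 2")
        var = x.var(axis=1, ddof=1)
        if np.any(var < VARIANCE_FLOOR):
            logger.warning("variance floored for %d channel(s) in band %s",
                           int(np.sum(var < VARIANCE_FLOOR)), name)
            var = np.maximum(var, VARIANCE_FLOOR)
        conv = _log_conv(log_base)
        chunks.append(0.5 * np.log(2.0 * np.pi * np.e * var) / conv)
    return np.concatenate(chunks)


def build_feature_matrix(segments: list[LabeledSegment],
                         bands: BandSet | None = None,
                         log_base=2) -> DEMatrix:
    """Band-decompose every segment and stack its DE vector into a matrix."""
    if not segments:
        raise ValueError("segment list is empty")
    bands = bands or BandSet()
    n_ch = segments[0].n_channels
    if any(s.n_channels != n_ch for s in segments):
        raise ValueError("segments have heterogeneous channel counts")
    band_order = bands.names
    rows = []
    meta_rows = []
    for seg in segments:
        banded = band_decompose_array(seg.data, seg.fs, bands)
        rows.append(segment_de(banded, log_base=log_base, band_order=band_order))
        meta_rows.append(
            {
                "class": seg.class_name,
                "valence": seg.valence_label,
                "arousal": seg.arousal_label,
                "trial_id": seg.trial_id,
                "window_index": seg.window_index,
            }
        )
    channel_labels = [f"ch{i:03d}" for i in range(n_ch)]
    return DEMatrix(
        values=np.vstack(rows),
        band_names=band_order,
        channel_labels=channel_labels,
        row_meta=pd.DataFrame(meta_rows),
        log_base=log_base,
    )


def select_bands(matrix: DEMatrix, subset: list[str]) -> DEMatrix:
    """Restrict columns to the chosen bands (order preserved as given)."""
    if not subset:
        raise ValueError("band subset must be non-empty")
    unknown = [b for b in subset if b not in matrix.band_names]
    if unknown:
        raise ValueError(f"unknown band name(s): {unknown}")
    cols = np.concatenate(
        [np.arange(matrix.n_channels) + matrix.band_names.index(b) * matrix.n_channels
         for b in subset]
    )
    return DEMatrix(
        values=matrix.values[:, cols],
        band_names=list(subset),
        channel_labels=list(matrix.channel_labels),
        row_meta=matrix.row_meta.reset_index(drop=True),
        log_base=matrix.log_base,
    )
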