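"""Continuous wavelet scalograms of EEG fragments.

Each single-channel fragment x(t) is mapped to its scalogram

    scalogram_x(a, tau) = |CWT_x(a, tau)|^2,
    CWT_x(a, tau) = (1/sqrt(a)) * integral x(t) Psi*((t - tau)/a) dt,

with Psi the complex Morlet wavelet Psi(u) = pi^(-1/4) exp(i w0 u - u^2/2)
(the small non-admissibility correction is negligible for the default
w0 = 6 and is omitted).  Scale a maps to pseudo-frequency f = w0 / (2 pi a).

The integral is evaluated as a Riemann sum on the signal's sample grid and
computed per scale as an FFT convolution with the sampled, conjugated
wavelet; the signal is implicitly zero-padded beyond its support.  The
cone of influence is not masked by default.

For classifier input the power image is mean-pooled onto a coarse grid
(default 16 x 16), flattened row-major, and min-max normalized to [0, 1]
per fragment so the downstream sigmoid autoencoders can treat entries as
probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import fftconvolve

SUPPORTED_MOTHERS = ("morlet",)
ACCEPTED_MOTHERS = ("morlet", "morse", "bump")


@dataclass
class WaveletConfig:
    """Parameters of the continuous wavelet transform.

    center_frequency_param is the Morlet w0 (dimensionless); n_scales scales
    are spaced (log by default) so their pseudo-frequencies cover
    [freq_min_hz, freq_max_hz], the latter defaulting to Nyquist.
    """

    mother: Literal["morlet", "morse", "bump"] = "morlet"
    center_frequency_param: float = 6.0
    n_scales: int = 32
    freq_min_hz: float = 1.0
    freq_max_hz: float | None = None
    scale_spacing: Literal["log", "linear"] = "log"

    def validate(self, fs: float) -> None:
        if self.mother not in ACCEPTED_MOTHERS:
            raise ValueError(f"unknown mother wavelet {self.mother!r}")
        if self.mother not in SUPPORTED_MOTHERS:
            raise NotImplementedError(
                f"mother wavelet {self.mother!r} is accepted in configuration "
                "but not provided by this wavelet backend; use 'morlet'"
            )
        if self.n_scales < 2:
            raise ValueError("n_scales must be at least 2")
        fmax = self.freq_max_hz if self.freq_max_hz is not None else fs / 2
        if not 0 < self.freq_min_hz < fmax <= fs / 2 + 1e-9:
            raise ValueError(
                f"need 0 < freq_min_hz < freq_max_hz <= fs/2, got "
                f"[{self.freq_min_hz}, {fmax}] at fs={fs}"
            )

    def frequencies(self, fs: float) -> np.ndarray:
        """Pseudo-frequency grid in Hz, ascending."""
        fmax = self.freq_max_hz if self.freq_max_hz is not None else fs / 2
        if self.scale_spacing == "log":
            return np.geomspace(self.freq_min_hz, fmax, self.n_scales)
        return np.linspace(self.freq_min_hz, fmax, self.n_scales)

    def scales(self, fs: float) -> np.ndarray:
        """Dilation a per row; a = w0 / (2 pi f)."""
        return self.center_frequency_param / (2 * np.pi * self.frequencies(fs))


@dataclass
class CWTCoefficients:
    """Complex CWT coefficients, one row per scale (rows ascend in frequency)."""

    coeffs: np.ndarray  # complex, (n_scales, n_timepoints)
    scales: np.ndarray
    freqs: np.ndarray


@dataclass
class Scalogram:
    """Squared-magnitude CWT power image of one fragment channel."""

    power: np.ndarray  # (n_scales, n_timepoints), nonnegative
    scales: np.ndarray
    freqs: np.ndarray


@dataclass
class ScalogramVector:
    """Pooled, flattened, per-fragment min-max normalized scalogram."""

    values: np.ndarray  # in [0, 1]^(rows*cols)
    grid: tuple[int, int]


def morlet(u: np.ndarray, w0: float = 6.0) -> np.ndarray:
    """Complex Morlet mother wavelet sampled at dimensionless argument u."""
    return np.pi ** -0.25 * np.exp(1j * w0 * u - 0.5 * u**2)


def cwt_transform(
    x: np.ndarray, fs: float, cfg: WaveletConfig | None = None
) -> CWTCoefficients:
    """Continuous wavelet transform of one channel on its own sample grid.

    Coefficients carry the 1/sqrt(a) normalization; row order matches
    ``cfg.frequencies(fs)`` (ascending).  NaN input is rejected.
    """
    cfg = cfg or WaveletConfig()
    cfg.validate(fs)
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("input must be a 1-D signal of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("input signal contains NaN or infinite samples")

    dt = 1.0 / fs
    scales = cfg.scales(fs)
    w0 = cfg.center_frequency_param
    rows = np.empty((len(scales), x.size), dtype=np.complex128)
    for i, a in enumerate(scales):
        # Gaussian envelope std in samples is a/dt; 8 stds keeps the truncated
        # tail below ~1e-14 of the peak.
        half = int(np.ceil(8.0 * a / dt))
        u = np.arange(-half, half + 1) * (dt / a)
        kernel = np.conj(morlet(u, w0))[::-1]
        rows[i] = fftconvolve(x, kernel, mode="same") * (dt / np.sqrt(a))
    return CWTCoefficients(rows, scales=scales, freqs=cfg.frequencies(fs))


def scalogram_power(coeffs: CWTCoefficients) -> Scalogram:
    """Elementwise squared magnitude of the CWT coefficients."""
    c = np.asarray(coeffs.coeffs)
    if not np.all(np.isfinite(c)):
        raise ValueError("coefficients must be finite")
    return Scalogram(np.abs(c) ** 2, scales=coeffs.scales, freqs=coeffs.freqs)


def vectorize_scalogram(
    s: Scalogram, grid: tuple[int, int] = (16, 16)
) -> ScalogramVector:
    """Mean-pool the power image onto ``grid``, flatten, min-max normalize.

    A constant image (max == min) maps to the all-zero vector with a warning
    instead of dividing by zero.
    """
    rows, cols = grid
    power = np.asarray(s.power, dtype=np.float64)
    if rows < 1 or cols < 1 or rows > power.shape[0] or cols > power.shape[1]:
        raise ValueError(
            f"pooling grid {grid} must fit within scalogram shape {power.shape}"
        )
    pooled = np.empty((rows, cols))
    row_blocks = np.array_split(np.arange(power.shape[0]), rows)
    col_blocks = np.array_split(np.arange(power.shape[1]), cols)
    for i, rb in enumerate(row_blocks):
        band = power[rb]
        for j, cb in enumerate(col_blocks):
            pooled[i, j] = band[:, cb].mean()
    flat = pooled.ravel()
    lo, hi = flat.min(), flat.max()
    if hi - lo < 1e-300:
        warnings.warn(
            "constant scalogram: normalized vector set to all zeros",
            stacklevel=2,
        )
        return ScalogramVector(np.zeros_like(flat), grid)
    return ScalogramVector((flat - lo) / (hi - lo), grid)


def fragment_to_vectors(
    samples: np.ndarray,
    fs: float,
    cfg: WaveletConfig | None = None,
    grid: tuple[int, int] = (16, 16),
) -> np.ndarray:
    """Per-channel scalogram vectors of one fragment; shape (C, rows*cols)."""
    samples = np.atleast_2d(samples)
    return np.stack([
        vectorize_scalogram(
            scalogram_power(cwt_transform(ch, fs, cfg)), grid
        ).values
        for ch in samples
    ])
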