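"""Synthetic annotated EEG with the structure the detector assumes.

Background activity is pink (1/f) noise per channel — mimicking the EEG
spectral slope so the wavelet stage is non-trivial — plus a little white
sensor noise.  Inside each seizure interval the background is multiplied by
``ictal_gain`` and a rhythmic theta-band sinusoid (default 7 Hz, random
phase per channel) of matching amplitude is added: the two ictal phenomena
the detector targets are increased amplitude and changed frequency
content.  Lowering ``ictal_gain`` toward 1 is the difficulty knob.

Everything is seeded and bitwise reproducible; no spike-wave morphology or
artifact (EMG/eye-blink) modeling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io_segmentation import EEGRecord, SeizureInterval


@dataclass
class SynthConfig:
    fs: float = 256.0
    n_channels: int = 4
    duration_s: float = 60.0
    background: float = 20.0        # pink-noise RMS amplitude, microvolts
    # explicit (start_s, end_s) intervals, or a float: the probability that
    # a record contains one randomly placed seizure
    ictal_intervals: Sequence[tuple[float, float]] | float = 0.5
    ictal_len_s: float = 8.0        # seizure length under random placement
    ictal_gain: float = 3.0         # amplitude multiplier inside seizures
    ictal_freq_hz: float = 7.0      # theta-band spike rhythm
    noise_sd: float = 2.0           # additive white noise, microvolts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ictal_gain <= 1:
            raise ValueError("ictal_gain must exceed 1")
        if self.fs <= 0 or self.n_channels < 1 or self.duration_s <= 0:
            raise ValueError("fs, n_channels and duration_s must be positive")
        if not isinstance(self.ictal_intervals, (int, float)):
            for s, e in self.ictal_intervals:
                if not 0 <= s < e <= self.duration_s:
                    raise ValueError(
                        f"ictal interval [{s}, {e}] outside the record"
                    )


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n)
    spectrum = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spectrum * shaping, n=n)
    return x / np.sqrt(np.mean(x**2))


def generate_record(cfg: SynthConfig, record_id: str = "synth-0") -> EEGRecord:
    """One annotated synthetic record, fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    if isinstance(cfg.ictal_intervals, (int, float)):
        intervals: list[tuple[float, float]] = []
        if rng.random() < float(cfg.ictal_intervals):
            length = min(cfg.ictal_len_s, cfg.duration_s)
            start = rng.uniform(0, cfg.duration_s - length)
            intervals.append((start, start + length))
    else:
        intervals = [tuple(iv) for iv in cfg.ictal_intervals]

    signal = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        background = cfg.background * _pink_noise(n, rng)
        x = background + cfg.noise_sd * rng.normal(size=n)
        for start, end in intervals:
            mask = (t >= start) & (t < end)
            phase = rng.uniform(0, 2 * np.pi)
            rhythm = np.sin(2 * np.pi * cfg.ictal_freq_hz * t[mask] + phase)
            x[mask] = (
                cfg.ictal_gain * background[mask]
                + cfg.ictal_gain * cfg.background * rhythm
                + cfg.noise_sd * rng.normal(size=mask.sum())
            )
        signal[c] = x

    annotations = [SeizureInterval(s, e) for s, e in intervals]
    return EEGRecord(signal, fs=cfg.fs, annotations=annotations,
                     record_id=record_id)


def generate_dataset(
    cfg: SynthConfig, n_records: int, seed: int | None = None
) -> list[EEGRecord]:
    """Independent records; record i uses seed ``seed + i`` (default cfg.seed)."""
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    base = cfg.seed if seed is None else seed
    return [
        generate_record(replace(cfg, seed=base + i), record_id=f"synth-{i:03d}")
        for i in range(n_records)
    ]


def default_study_dataset(seed: int = 0, n_records: int = 10) -> list[EEGRecord]:
    """The default end-to-end evaluation set: ten 30 s 4-channel records,
    one 8 s seizure each at a seeded random position.

    Segmented at 3 s / 1 s this yields ~100 ictal and ~180 non-ictal
    fragments, i.e. about 200 fragments after class balancing.
    """
    cfg = SynthConfig(duration_s=30.0, ictal_intervals=1.0, seed=seed)
    return generate_dataset(cfg, n_records, seed=seed)
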