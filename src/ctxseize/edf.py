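"""Minimal EDF (European Data Format) writer.

Writes plain EDF (not EDF+): fixed-width ASCII headers followed by
little-endian int16 samples. Intended for exporting synthetic records and
for round-trip testing against the EDF reader; amplitudes are quantized to
the 16-bit digital range over each channel's physical min/max, so a
write/read round trip agrees to within one quantization step.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .io_segmentation import EEGRecord

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    text = value[:width].ljust(width)
    return text.encode("ascii")


def write_edf(record: EEGRecord, path: str | Path) -> None:
    """Write a record as EDF with one int16 data stream per channel.

    If the sample count divides into whole 1-second records the file uses
    1-second data records; otherwise a single data record holds the whole
    signal (legal EDF, and what the paired reader expects).
    """
    path = Path(path)
    signal = np.asarray(record.signal, dtype=np.float64)
    n_ch, n_samp = signal.shape
    fs = record.fs
    spr = int(fs) if float(fs).is_integer() and n_samp % int(fs) == 0 else n_samp
    n_records = n_samp // spr
    record_dur = spr / fs

    phys_min = signal.min(axis=1)
    phys_max = signal.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((signal - phys_min[:, None]) / scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join([
        _field("0", 8),                                   # version
        _field("X X X X", 80),                            # patient id
        _field("Startdate X X X X", 80),                  # recording id
        _field("01.01.00", 8),                            # start date
        _field("00.00.00", 8),                            # start time
        _field(str(256 + 256 * n_ch), 8),                 # header bytes
        _field("", 44),                                   # reserved
        _field(str(n_records), 8),
        _field(_format_duration(record_dur), 8),
        _field(str(n_ch), 4),
    ])

    def block(values: list[str], width: int) -> bytes:
        return b"".join(_field(v, width) for v in values)

    sig_header = b"".join([
        block(record.channel_names, 16),
        block([""] * n_ch, 80),                           # transducer
        block(["uV"] * n_ch, 8),                          # physical dimension
        block([_format_phys(v) for v in phys_min], 8),
        block([_format_phys(v) for v in phys_max], 8),
        block([str(_DIG_MIN)] * n_ch, 8),
        block([str(_DIG_MAX)] * n_ch, 8),
        block([""] * n_ch, 80),                           # prefiltering
        block([str(spr)] * n_ch, 8),
        block([""] * n_ch, 32),                           # reserved
    ])

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            chunk = digital[:, r * spr : (r + 1) * spr]
            fh.write(chunk.tobytes())  # channel-by-channel within each record


def _format_duration(seconds: float) -> str:
    if float(seconds).is_integer():
        return str(int(seconds))
    return f"{seconds:.6f}"[:8].rstrip("0")


def _format_phys(value: float) -> str:
    for fmt in (f"{value:.6g}", f"{value:.4g}", f"{value:.2g}"):
        if len(fmt) <= 8 and math.isfinite(value):
            return fmt
    return f"{value:.1e}"[:8]
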