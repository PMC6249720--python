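"""Reading, segmenting, labeling and splitting annotated EEG records.

Records come in two on-disk shapes: EDF (multi-channel scalp EEG, e.g. the
CHB-MIT corpus) and Bonn-style single-column ASCII (one amplitude sample per
line).  Seizure annotations travel in a sidecar TSV with columns
``record_id, start_s, end_s``.

Segmentation slides a fixed-length window (default 3 s) with a fixed step
(default 1 s) across each record.  Window and step lengths are converted to
sample counts with ``floor``, so a 23.6 s Bonn record at 173.61 Hz yields a
520-sample window, a 173-sample step, and 21 fragments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ICTAL = "ictal"
NON_ICTAL = "non_ictal"
UNLABELED = "unlabeled"

_LABELS = (ICTAL, NON_ICTAL, UNLABELED)


class EDFFormatError(ValueError):
    """Raised when an EDF file is malformed or truncated."""


class UnsupportedEDFError(ValueError):
    """Raised for EDF dialects the reader does not support (e.g. mixed rates)."""


@dataclass(frozen=True)
class SeizureInterval:
    """One expert-annotated seizure, in seconds from record start."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"invalid seizure interval [{self.start_s}, {self.end_s}]: "
                "need 0 <= start < end"
            )


@dataclass
class EEGRecord:
    """A multi-channel EEG time series with seizure annotations.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    annotations : list of SeizureInterval
    record_id : str
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    annotations: list[SeizureInterval] = field(default_factory=list)
    record_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim == 1:
            self.signal = self.signal[np.newaxis, :]
        if self.signal.ndim != 2 or self.signal.shape[0] < 1:
            raise ValueError("signal must be a (channels, timepoints) matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{c}" for c in range(self.signal.shape[0])]
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match channel count")
        for iv in self.annotations:
            if iv.end_s > self.duration_s + 1e-9:
                raise ValueError(
                    f"annotation [{iv.start_s}, {iv.end_s}] exceeds record "
                    f"duration {self.duration_s:.3f} s"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs


@dataclass
class Fragment:
    """One windowed slice of a record, the unit the detector classifies."""

    samples: np.ndarray  # (channels, window_timepoints)
    start_s: float
    label: str = UNLABELED
    record_id: str = ""
    index_in_record: int = 0  # the timestamp t of the fragment within its record

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


@dataclass
class FragmentSequence:
    """The ordered fragments of one record, with the segmentation geometry."""

    fragments: list[Fragment]
    window_s: float
    step_s: float
    fs: float
    record_id: str = ""

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def __getitem__(self, i):
        return self.fragments[i]


@dataclass
class SplitDataset:
    """Balanced, stratified 4:1 hold-out split of labeled fragments."""

    train: list[Fragment]
    test: list[Fragment]
    seed: int


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_ascii_record(path: str | Path, fs: float, record_id: str | None = None) -> EEGRecord:
    """Read a Bonn-style single-column ASCII record (one sample per line).

    Raises a ``ValueError`` naming the offending line number on non-numeric
    input, and on an empty file.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {text!r} on line {lineno}"
                ) from None
    if not values:
        raise ValueError(f"{path}: empty record file")
    rid = record_id if record_id is not None else path.stem
    return EEGRecord(np.asarray(values)[np.newaxis, :], fs=fs, record_id=rid)


def _edf_signal_headers(path: Path) -> tuple[int, list[int]]:
    """Parse just enough of the EDF header to validate it.

    Returns (n_signals, samples_per_record per signal). EDF headers are
    fixed-width ASCII, so this is a cheap pre-flight check before handing the
    file to mne.
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise EDFFormatError(f"{path}: truncated EDF header")
        try:
            n_signals = int(header[252:256].decode("ascii").strip())
            header_bytes = int(header[184:192].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise EDFFormatError(f"{path}: malformed EDF header") from exc
        if n_signals < 1 or header_bytes != 256 + 256 * n_signals:
            raise EDFFormatError(f"{path}: inconsistent EDF header sizes")
        sig_header = fh.read(256 * n_signals)
        if len(sig_header) < 256 * n_signals:
            raise EDFFormatError(f"{path}: truncated EDF signal headers")
        # samples-per-record field: ns*8 chars at offset 216*ns within the block
        off = 216 * n_signals
        try:
            spr = [
                int(sig_header[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
                for i in range(n_signals)
            ]
        except (UnicodeDecodeError, ValueError) as exc:
            raise EDFFormatError(f"{path}: malformed samples-per-record field") from exc
    return n_signals, spr


def read_edf_record(path: str | Path, record_id: str | None = None) -> EEGRecord:
    """Read a multi-channel EDF record (amplitudes returned in microvolts).

    Annotations are *not* read from the file; attach them separately from the
    sidecar TSV (see :func:`read_annotations_tsv` / :func:`label_fragments`).
    Channels sampled at different rates are rejected as an unsupported
    dialect.
    """
    path = Path(path)
    n_signals, spr = _edf_signal_headers(path)
    if len(set(spr)) > 1:
        raise UnsupportedEDFError(
            f"{path}: channels with differing sampling rates are not supported"
        )
    import mne  # deferred: mne import is slow

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data_uv = raw.get_data(units="uV")
    except (EDFFormatError, UnsupportedEDFError):
        raise
    except Exception as exc:  # mne raises assorted types on malformed files
        raise EDFFormatError(f"{path}: cannot read EDF file ({exc})") from exc
    rid = record_id if record_id is not None else path.stem
    return EEGRecord(
        data_uv,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        record_id=rid,
    )


def read_annotations_tsv(path: str | Path) -> dict[str, list[SeizureInterval]]:
    """Read the seizure-interval sidecar: TSV columns record_id, start_s, end_s."""
    out: dict[str, list[SeizureInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: expected 3 TSV columns on line {lineno}")
            if lineno == 1 and parts[0] == "record_id":
                continue  # header
            rid, start_s, end_s = parts
            out.setdefault(rid, []).append(
                SeizureInterval(float(start_s), float(end_s))
            )
    return out


def write_annotations_tsv(
    path: str | Path, annotations: dict[str, Sequence[SeizureInterval]]
) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tstart_s\tend_s\n")
        for rid, ivs in annotations.items():
            for iv in ivs:
                fh.write(f"{rid}\t{iv.start_s:.6f}\t{iv.end_s:.6f}\n")


# ---------------------------------------------------------------------------
# Segmentation and labeling
# ---------------------------------------------------------------------------

def segment_record(
    record: EEGRecord, window_s: float = 3.0, step_s: float = 1.0
) -> FragmentSequence:
    """Slide a fixed window over the record and cut unlabeled fragments.

    Fragment count is ``floor((n_samples - window_samples)/step_samples) + 1``.
    A record shorter than one window yields an empty sequence and a logged
    warning rather than an exception.
    """
    if window_s <= 0 or step_s <= 0:
        raise ValueError("window_s and step_s must be positive")
    window_n = int(math.floor(window_s * record.fs))
    step_n = int(math.floor(step_s * record.fs))
    if window_n < 1 or step_n < 1:
        raise ValueError("window and step must span at least one sample")
    n = record.n_samples
    if n < window_n:
        logger.warning(
            "record %s (%.2f s) is shorter than the %.2f s window; "
            "no fragments produced",
            record.record_id, record.duration_s, window_s,
        )
        return FragmentSequence([], window_s, step_s, record.fs, record.record_id)
    count = (n - window_n) // step_n + 1
    fragments = [
        Fragment(
            samples=record.signal[:, i * step_n : i * step_n + window_n],
            start_s=i * step_n / record.fs,
            record_id=record.record_id,
            index_in_record=i,
        )
        for i in range(count)
    ]
    return FragmentSequence(fragments, window_s, step_s, record.fs, record.record_id)


def merge_intervals(
    intervals: Iterable[SeizureInterval],
) -> list[SeizureInterval]:
    """Merge overlapping or touching seizure intervals into disjoint ones."""
    ivs = sorted(intervals, key=lambda iv: (iv.start_s, iv.end_s))
    merged: list[SeizureInterval] = []
    for iv in ivs:
        if merged and iv.start_s <= merged[-1].end_s:
            if iv.end_s > merged[-1].end_s:
                merged[-1] = SeizureInterval(merged[-1].start_s, iv.end_s)
        else:
            merged.append(iv)
    return merged


def label_fragments(
    seq: FragmentSequence,
    annotations: Sequence[SeizureInterval],
    min_overlap_fraction: float = 0.0,
) -> FragmentSequence:
    """Label each fragment ictal/non-ictal from seizure intervals.

    A fragment is ictal iff its window overlaps some (merged) seizure
    interval by strictly more than ``min_overlap_fraction * window_s``
    seconds; with the default 0 this is the any-positive-overlap rule.
    """
    if not 0 <= min_overlap_fraction <= 1:
        raise ValueError("min_overlap_fraction must lie in [0, 1]")
    duration = None
    if seq.fragments:
        duration = seq.fragments[-1].start_s + seq.window_s
    for iv in annotations:
        if duration is not None and iv.start_s >= duration:
            raise ValueError(
                f"seizure interval [{iv.start_s}, {iv.end_s}] lies outside the "
                "segmented extent of the record"
            )
    merged = merge_intervals(annotations)
    threshold = min_overlap_fraction * seq.window_s
    labeled = []
    for frag in seq.fragments:
        w0, w1 = frag.start_s, frag.start_s + seq.window_s
        overlap = max(
            (min(w1, iv.end_s) - max(w0, iv.start_s) for iv in merged),
            default=0.0,
        )
        label = ICTAL if overlap > threshold else NON_ICTAL
        labeled.append(replace(frag, label=label))
    return FragmentSequence(labeled, seq.window_s, seq.step_s, seq.fs, seq.record_id)


def balance_and_split(
    fragments: Sequence[Fragment], ratio: float = 0.8, seed: int = 0
) -> SplitDataset:
    """Balance classes by down-sampling, then split 4:1 stratified by class.

    The majority class is randomly down-sampled (seeded) to the minority
    count; each class is then independently shuffled and divided so the train
    share is ``ratio``, keeping both folds balanced.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    by_label: dict[str, list[int]] = {ICTAL: [], NON_ICTAL: []}
    for i, frag in enumerate(fragments):
        if frag.label in by_label:
            by_label[frag.label].append(i)
    for lbl in (ICTAL, NON_ICTAL):
        if not by_label[lbl]:
            raise ValueError(f"cannot balance: no fragments of class {lbl!r}")
    rng = np.random.default_rng(seed)
    n_keep = min(len(by_label[ICTAL]), len(by_label[NON_ICTAL]))
    train_idx: list[int] = []
    test_idx: list[int] = []
    for lbl in (ICTAL, NON_ICTAL):
        idx = np.asarray(by_label[lbl])
        kept = rng.choice(idx, size=n_keep, replace=False)
        rng.shuffle(kept)
        n_train = int(round(n_keep * ratio))
        train_idx.extend(kept[:n_train].tolist())
        test_idx.extend(kept[n_train:].tolist())
    rng.shuffle(train_idx)
    rng.shuffle(test_idx)
    return SplitDataset(
        train=[fragments[i] for i in train_idx],
        test=[fragments[i] for i in test_idx],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Fragment container persistence (the pipeline's NPZ interchange format)
# ---------------------------------------------------------------------------

def save_fragments(path: str | Path, fragments: Sequence[Fragment],
                   window_s: float, step_s: float, fs: float) -> None:
    """Persist fragments plus their metadata to an ``.npz`` container."""
    if not fragments:
        raise ValueError("nothing to save: empty fragment collection")
    samples = np.stack([f.samples for f in fragments])
    np.savez_compressed(
        path,
        samples=samples,
        start_s=np.array([f.start_s for f in fragments]),
        label=np.array([f.label for f in fragments]),
        record_id=np.array([f.record_id for f in fragments]),
        index_in_record=np.array([f.index_in_record for f in fragments]),
        window_s=window_s,
        step_s=step_s,
        fs=fs,
    )


def load_fragments(path: str | Path) -> tuple[list[Fragment], dict]:
    """Load fragments from the NPZ container; returns (fragments, meta)."""
    with np.load(path, allow_pickle=False) as npz:
        fragments = [
            Fragment(
                samples=npz["samples"][i],
                start_s=float(npz["start_s"][i]),
                label=str(npz["label"][i]),
                record_id=str(npz["record_id"][i]),
                index_in_record=int(npz["index_in_record"][i]),
            )
            for i in range(npz["samples"].shape[0])
        ]
        meta = {
            "window_s": float(npz["window_s"]),
            "step_s": float(npz["step_s"]),
            "fs": float(npz["fs"]),
        }
    return fragments, meta
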