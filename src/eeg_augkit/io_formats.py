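"""Readers, writers and signal conditioning for the two real-data pathways.

Two on-disk dialects are supported:

* **two-column ASCII** — one iEEG segment per file, two numeric columns
  (comma or whitespace separated), one row per sample at 512 Hz;
* **EDF/EDF+** — polysomnography recordings read through :mod:`mne`, with
  hypnogram annotations from either an EDF+ annotation file or a plain CSV
  (``onset_s,duration_s,stage``). A minimal 16-bit EDF *writer* is included so
  fixtures can be produced without any external dataset.

Conditioning follows the standard recipe for sleep EEG: 0.1–50 Hz zero-phase
band-pass, segmentation into 30-s epochs along the hypnogram, and per-channel
z-scoring. All preprocessing is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .segment import EEGSegment

logger = logging.getLogger(__name__)

#: R&K / AASM stage vocabulary normalisation (R&K stage 4 folds into N3)
STAGE_VOCABULARY = {
    "Sleep stage W": "Wake", "Sleep stage 1": "N1", "Sleep stage 2": "N2",
    "Sleep stage 3": "N3", "Sleep stage 4": "N3", "Sleep stage R": "REM",
    "W": "Wake", "Wake": "Wake", "N1": "N1", "N2": "N2", "N3": "N3",
    "N4": "N3", "R": "REM", "REM": "REM",
}


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass
class HypnogramAnnotation:
    """Sleep-stage annotations: onsets and durations in seconds from start."""

    onsets: np.ndarray
    durations: np.ndarray
    stages: list[str]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if not (len(self.onsets) == len(self.durations) == len(self.stages)):
            raise ValueError("onsets, durations and stages must have equal length")
        if np.any(np.diff(self.onsets) < 0):
            raise ValueError("annotation onsets must be non-decreasing")
        if np.any(self.durations <= 0):
            raise ValueError("annotation durations must be positive")
        unknown = [s for s in self.stages if s not in STAGE_VOCABULARY]
        if unknown:
            raise ValueError(f"unknown stage labels {sorted(set(unknown))}; "
                             f"known: {sorted(set(STAGE_VOCABULARY))}")
        self.stages = [STAGE_VOCABULARY[s] for s in self.stages]


# ---------------------------------------------------------------------------
# two-column ASCII (iEEG segment dialect)
# ---------------------------------------------------------------------------

def read_two_column_ascii(path: str | Path, fs: float = 512.0) -> EEGSegment:
    """Read one two-channel segment; row t maps to sample index t (0-based)."""
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(tokens)}")
            try:
                rows.append((float(tokens[0]), float(tokens[1])))
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric token in {tokens}") from None
    if len(rows) < 2:
        raise ParseError(f"{path}: need at least 2 rows, got {len(rows)}")
    data = np.asarray(rows).T  # (2, n_samples)
    return EEGSegment(data=data, fs=fs, label=-1,
                      channel_names=["x", "y"], source_id=str(path))


def write_two_column_ascii(path: str | Path, seg: EEGSegment) -> None:
    """Inverse of :func:`read_two_column_ascii` (repr round-trips bit-exactly)."""
    if seg.n_channels != 2:
        raise ValueError(f"ASCII dialect is two-channel, segment has {seg.n_channels}")
    with open(path, "w") as fh:
        for a, b in seg.data.T:
            fh.write(f"{float(a)!r},{float(b)!r}\n")


# ---------------------------------------------------------------------------
# EDF (16-bit) writing and reading
# ---------------------------------------------------------------------------

def write_edf(path: str | Path, data: np.ndarray, fs: float,
              channel_names: list[str]) -> None:
    """Write a minimal EDF file (one data record per second, 16-bit).

    Intended for producing small test fixtures; values round-trip to within
    the 16-bit quantisation of the per-channel physical range.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("one channel name per row required")
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("integer sampling rate required by this writer")
    fs = int(round(fs))
    if n_samp % fs:
        raise ValueError("signal length must be a whole number of seconds")
    n_rec = n_samp // fs

    def f(text: str, width: int) -> bytes:
        b = str(text)[:width].encode("ascii")
        return b + b" " * (width - len(b))

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    # guard degenerate ranges
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate X X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8), f(str(256 * (1 + n_ch)), 8),
        f("", 44), f(str(n_rec), 8), f("1", 8), f(str(n_ch), 4),
    ])
    header += b"".join(f(name, 16) for name in channel_names)
    header += b"".join(f("", 80) for _ in range(n_ch))          # transducer
    header += b"".join(f("uV", 8) for _ in range(n_ch))          # dimension
    header += b"".join(f(f"{v:.6g}", 8) for v in phys_min)
    header += b"".join(f(f"{v:.6g}", 8) for v in phys_max)
    header += b"".join(f(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(f(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(f("", 80) for _ in range(n_ch))           # prefiltering
    header += b"".join(f(str(fs), 8) for _ in range(n_ch))
    header += b"".join(f("", 32) for _ in range(n_ch))

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            chunk = digital[:, r * fs:(r + 1) * fs]
            fh.write(chunk.tobytes())  # channel-major within the record


def write_hypnogram_csv(path: str | Path, annotation: HypnogramAnnotation) -> None:
    with open(path, "w") as fh:
        fh.write("onset_s,duration_s,stage\n")
        for onset, dur, stage in zip(annotation.onsets, annotation.durations,
                                     annotation.stages):
            fh.write(f"{float(onset)!r},{float(dur)!r},{stage}\n")


def read_hypnogram(path: str | Path) -> HypnogramAnnotation:
    """Read hypnogram annotations from CSV or an EDF+ annotation file."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        onsets, durations, stages = [], [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("onset"):
                raise ParseError(f"{path}: line 1: expected header 'onset_s,duration_s,stage'")
            for lineno, line in enumerate(fh, start=2):
                line = line.strip()
                if not line:
                    continue
                tokens = line.split(",")
                if len(tokens) != 3:
                    raise ParseError(f"{path}: line {lineno}: expected 3 columns")
                onsets.append(float(tokens[0]))
                durations.append(float(tokens[1]))
                stages.append(tokens[2])
        return HypnogramAnnotation(onsets, durations, stages)
    import mne

    ann = mne.read_annotations(str(path))
    return HypnogramAnnotation(ann.onset, ann.duration, list(ann.description))


def read_edf_with_hypnogram(recording_path: str | Path,
                            annotation_path: str | Path,
                            channels: list[str]
                            ) -> tuple[np.ndarray, float, HypnogramAnnotation]:
    """Load selected EDF channels (by label, order-independent) + hypnogram.

    Returns ``(signals, fs, annotation)`` with signals of shape
    ``(len(channels), n_samples)`` in the order requested.
    """
    import mne

    raw = mne.io.read_raw_edf(str(recording_path), preload=True, verbose="error")
    available = list(raw.ch_names)
    missing = [c for c in channels if c not in available]
    if missing:
        raise KeyError(f"channel(s) {missing} not in recording; available: {available}")
    data = raw.get_data(picks=channels)
    annotation = read_hypnogram(annotation_path)
    return np.asarray(data), float(raw.info["sfreq"]), annotation


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def epoch_by_hypnogram(signals: np.ndarray, fs: float,
                       annotation: HypnogramAnnotation, epoch_s: float = 30.0,
                       channel_names: list[str] | None = None
                       ) -> list[EEGSegment]:
    """Cut half-open ``[t, t + epoch_s)`` windows along the hypnogram.

    Each annotation interval contributes ``floor(duration / epoch_s)`` epochs
    labelled with the interval's stage. Epochs extending past the recording or
    containing non-finite values are dropped (and logged with the reason).
    """
    from .synthetic import STAGE_TO_ID

    signals = np.atleast_2d(np.asarray(signals))
    n_samp = signals.shape[1]
    epochs: list[EEGSegment] = []
    win = int(round(epoch_s * fs))
    for onset, dur, stage in zip(annotation.onsets, annotation.durations,
                                 annotation.stages):
        for m in range(int(np.floor(dur / epoch_s))):
            start = int(round((onset + m * epoch_s) * fs))
            stop = start + win
            if stop > n_samp:
                logger.info("dropping epoch at %.1fs: extends past the recording",
                            onset + m * epoch_s)
                continue
            window = signals[:, start:stop]
            if not np.all(np.isfinite(window)):
                logger.info("dropping epoch at %.1fs: non-finite values",
                            onset + m * epoch_s)
                continue
            epochs.append(EEGSegment(
                data=window.copy(), fs=fs, label=STAGE_TO_ID[stage],
                channel_names=list(channel_names) if channel_names else [],
                source_id=f"epoch@{onset + m * epoch_s:.0f}s"))
    return epochs


def bandpass(seg: EEGSegment, low: float = 0.1, high: float = 50.0,
             order: int = 4) -> EEGSegment:
    """Zero-phase Butterworth band-pass (forward-backward second-order sections)."""
    nyq = seg.fs / 2
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    sos = sp_signal.butter(order, [low, high], btype="bandpass", fs=seg.fs,
                           output="sos")
    return seg.with_data(sp_signal.sosfiltfilt(sos, seg.data, axis=1))


def zscore_per_channel(seg: EEGSegment) -> EEGSegment:
    """Normalise each channel to sample mean 0 and sample (ddof=1) std 1."""
    mean = seg.data.mean(axis=1, keepdims=True)
    std = seg.data.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(std.ravel() < 1e-15)
    if len(flat):
        names = [seg.channel_names[i] for i in flat]
        raise ValueError(f"zero-variance channel(s) {names}: flat channels indicate "
                         "a recording failure and cannot be z-scored")
    return seg.with_data((seg.data - mean) / std)
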