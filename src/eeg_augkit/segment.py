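"""The labelled multi-channel signal window that every stage of the toolkit consumes."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class EEGSegment:
    """One labelled EEG/iEEG window — the unit of classification.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values in microvolts (or z-scored units after preprocessing).
    fs : float
        Sampling rate in Hz.
    label : int
        Integer class id (task-dependent: sleep stage or focal/non-focal).
    channel_names : list of str
        One name per row of ``data``.
    source_id : str
        Opaque provenance tag (subject/segment identifier); used by the
        cross-validation leakage guard.
    """

    data: np.ndarray
    fs: float
    label: int
    channel_names: list[str] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 1:
            self.data = self.data[np.newaxis, :]
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        n_ch, n_samp = self.data.shape
        if n_ch < 1 or n_samp < 2:
            raise ValueError(f"segment needs >=1 channel and >=2 samples, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("segment contains non-finite values")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(n_ch)]
        if len(self.channel_names) != n_ch:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_ch} channels"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "EEGSegment":
        """Copy of this segment with new sample values; all metadata kept."""
        return replace(self, data=data)

    def copy(self) -> "EEGSegment":
        return replace(self, data=self.data.copy(), channel_names=list(self.channel_names))
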