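"""In-memory container for multichannel electrophysiology (EEG / EMG)."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEGRecording"]


@dataclass
class EEGRecording:
    """A continuous multichannel recording in microvolts.

    Attributes
    ----------
    channels : list of str
        Channel labels, one per row of ``samples``.
    sample_rate : float
        Sampling rate in Hz.
    samples : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    annotations : list of (onset_seconds, label)
        Event markers, onsets relative to recording start.
    """

    channels: list[str]
    sample_rate: float
    samples: np.ndarray
    annotations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"samples shape {self.samples.shape} inconsistent with "
                f"{len(self.channels)} channels"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        dur = self.duration
        for onset, label in self.annotations:
            if not (0 <= onset <= dur):
                raise ValueError(f"annotation {label!r} at {onset} s outside recording")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def get_channel(self, label: str) -> np.ndarray:
        if label not in self.channels:
            raise KeyError(f"channel {label!r} not in recording ({self.channels})")
        return self.samples[self.channels.index(label)]

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            channels=list(self.channels),
            sample_rate=self.sample_rate,
            samples=self.samples.copy(),
            annotations=list(self.annotations),
        )
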