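"""Core in-memory containers shared across the package.

Conventions
-----------
* Voltage data are ``(n_channels, n_samples)`` float64 arrays.
* Sample indices are 0-based; event intervals are half-open ``[start, end)``.
* Band-limited phase follows ``x(t) = A(t) * cos(phi(t))`` so that the
  trough of the band-passed signal corresponds to ``phi = pi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesRecording",
    "TrialTable",
    "SpikeTrain",
    "RippleEvent",
    "events_to_frame",
    "GroundTruth",
    "SyntheticSession",
]


@dataclass
class TimeSeriesRecording:
    """Multichannel voltage time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage samples (arbitrary units; consistent within a session).
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Channel labels.
    scale : str
        Spatial scale tag: ``"ieeg"`` (macro) or ``"lfp"`` (micro).
    """

    data: np.ndarray
    fs: float
    channels: list[str] = field(default_factory=list)
    scale: str = "ieeg"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channels:
            self.channels = [f"{self.scale}{i}" for i in range(self.data.shape[0])]
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel labels do not match data shape")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "TimeSeriesRecording":
        return TimeSeriesRecording(self.data.copy(), self.fs, list(self.channels), self.scale)


@dataclass
class TrialTable:
    """Per-trial epoch boundaries with an alignment point and outcome label.

    ``start``/``end`` delimit the trial epoch in samples (half-open);
    ``align`` is the within-session sample of the alignment event
    (vocalization onset in the memory-retrieval design the simulator
    emulates).  ``label`` is one of ``correct``, ``incorrect`` or ``pass``.
    """

    start: np.ndarray
    end: np.ndarray
    align: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.align = np.asarray(self.align, dtype=np.int64)
        self.label = np.asarray(self.label, dtype=object)
        n = len(self.start)
        if not (len(self.end) == len(self.align) == len(self.label) == n):
            raise ValueError("trial table columns must have equal length")
        if np.any(self.end <= self.start):
            raise ValueError("trial end must exceed trial start")

    @property
    def n_trials(self) -> int:
        return len(self.start)

    def mask(self, label: str) -> np.ndarray:
        return self.label == label

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start": self.start, "end": self.end, "align": self.align, "label": self.label}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialTable":
        return cls(
            df["start"].to_numpy(), df["end"].to_numpy(),
            df["align"].to_numpy(), df["label"].to_numpy(),
        )


@dataclass
class SpikeTrain:
    """Spike times for one unit, as sample indices into the session clock."""

    unit: str
    indices: np.ndarray
    channel: int = 0
    waveforms: np.ndarray | None = None  # (n_spikes, 32) if present

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("spike indices must be strictly increasing")
        if self.waveforms is not None:
            self.waveforms = np.asarray(self.waveforms, dtype=float)
            if self.waveforms.shape[0] != self.indices.size:
                raise ValueError("one waveform per spike required")

    @property
    def n_spikes(self) -> int:
        return self.indices.size


@dataclass
class RippleEvent:
    """One detected band-limited oscillatory event.

    ``start``/``end`` are the envelope-threshold crossing samples (half-open
    interval), ``peak_sample`` the sample of maximal envelope z-score and
    ``peak_z`` that maximum, in SD units of the session envelope.
    """

    channel: int
    start: int
    end: int
    peak_sample: int
    peak_z: float
    fs: float
    band: tuple[float, float] = (80.0, 120.0)

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) / self.fs * 1000.0

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def events_to_frame(events: Sequence[RippleEvent]) -> pd.DataFrame:
    """Tabulate detected events (one row per event) for TSV/CSV export."""
    rows = [
        {
            "channel": e.channel,
            "start_s": e.start / e.fs,
            "end_s": e.end / e.fs,
            "start_sample": e.start,
            "end_sample": e.end,
            "duration_ms": e.duration_ms,
            "peak_z": e.peak_z,
            "peak_sample": e.peak_sample,
            "band_lo": e.band[0],
            "band_hi": e.band[1],
        }
        for e in events
    ]
    cols = ["channel", "start_s", "end_s", "start_sample", "end_sample",
            "duration_ms", "peak_z", "peak_sample", "band_lo", "band_hi"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class GroundTruth:
    """Simulator-emitted ground truth for recovery tests.

    ``events`` has one row per (channel, event) occurrence with columns
    ``channel, start, end, peak_sample, freq, amplitude, shared_id`` where
    ``amplitude`` is the intended peak envelope z-score (envelope above its
    mean, in SDs of the band-passed background trace) and ``shared_id >= 0``
    marks events shared (time- and phase-aligned) across all micro channels.
    """

    events: pd.DataFrame
    ied_times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    spike_lock_phase: float = np.pi
    spike_counts: dict = field(default_factory=dict)

    def channel_events(self, channel: int) -> pd.DataFrame:
        return self.events[self.events["channel"] == channel]

    def shared_events(self) -> pd.DataFrame:
        """One row per shared event (deduplicated across channels)."""
        shared = self.events[self.events["shared_id"] >= 0]
        return shared.drop_duplicates(subset="shared_id")


@dataclass
class SyntheticSession:
    """Everything one simulated session produces."""

    ieeg: TimeSeriesRecording
    lfp: TimeSeriesRecording
    spikes: list[SpikeTrain]
    trials: TrialTable
    truth: GroundTruth
    config: object = None
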