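"""Core in-memory containers shared across the pipeline.

``Waveform`` is a uniformly sampled single-channel signal (mV);
``BeatSeries`` holds detected R-peak times; ``RRSeries`` the successive
inter-beat intervals with per-interval quality flags.  Intervals are kept
in seconds throughout (converters to/from ms are provided because
acquisition software often reports ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

FLAG_OK = 0
FLAG_REJECTED = 1


@dataclass
class Waveform:
    samples: np.ndarray  # mV
    fs: float  # Hz
    channel_label: str = ""
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n) / self.fs

    def copy_with(self, samples: np.ndarray) -> "Waveform":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class BeatSeries:
    """Strictly ascending R-peak times, seconds from recording start."""

    beat_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.beat_times_s.size > 1 and not np.all(
            np.diff(self.beat_times_s) > 0
        ):
            raise ValueError("beat times must be strictly ascending")

    @property
    def n(self) -> int:
        return self.beat_times_s.size


@dataclass
class RRSeries:
    """Successive inter-beat intervals (s) with quality flags.

    ``interval_end_times_s[i]`` is the time of the beat closing interval i;
    flagged (rejected) intervals are excluded from every metric.
    """

    intervals_s: np.ndarray
    interval_end_times_s: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intervals_s = np.asarray(self.intervals_s, dtype=float)
        self.interval_end_times_s = np.asarray(
            self.interval_end_times_s, dtype=float
        )
        if self.flags is None:
            self.flags = np.zeros(self.intervals_s.size, dtype=int)
        self.flags = np.asarray(self.flags, dtype=int)
        if not (
            self.intervals_s.size
            == self.interval_end_times_s.size
            == self.flags.size
        ):
            raise ValueError("RRSeries field lengths differ")
        if np.any(self.intervals_s <= 0):
            raise ValueError("RR intervals must be positive")

    @property
    def n(self) -> int:
        return self.intervals_s.size

    @property
    def accepted(self) -> np.ndarray:
        """Boolean mask of intervals usable for metrics."""
        return self.flags == FLAG_OK

    def accepted_intervals(self) -> np.ndarray:
        return self.intervals_s[self.accepted]

    @classmethod
    def empty(cls) -> "RRSeries":
        return cls(np.empty(0), np.empty(0), np.empty(0, dtype=int))


def rr_to_ms(intervals_s: np.ndarray) -> np.ndarray:
    return np.asarray(intervals_s, dtype=float) * 1000.0


def rr_from_ms(intervals_ms: np.ndarray) -> np.ndarray:
    return np.asarray(intervals_ms, dtype=float) / 1000.0


@dataclass
class HRVSummary:
    """Per-subject per-window time-domain HRV summary.

    Metrics are ``None`` (missing), never zero, when the window holds
    fewer than three accepted beats.
    """

    subject_id: str
    window: str
    hr_bpm: float | None
    rr_mean_s: float | None
    rmssd_s: float | None
    sdnn_s: float | None
    n_beats: int
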