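"""Core data containers shared across the pipeline.

Everything downstream of raw ECG works in seconds: R-peak positions are
sample indices tied to a sampling frequency, while R-R intervals are
durations in seconds so that records digitised at different rates feed the
same classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ECGRecord",
    "SyntheticECG",
    "RhythmInterval",
    "RhythmTrack",
    "RPeakSeries",
    "RRSequence",
    "RRWindow",
]

#: Rhythm labels: N = normal sinus, AFIB = atrial fibrillation,
#: AFL = atrial flutter, J = junctional (AV-junction) rhythm.
RHYTHM_LABELS = ("N", "AFIB", "AFL", "J")


@dataclass
class ECGRecord:
    """A single-lead sampled ECG voltage trace."""

    record_id: str
    samples: np.ndarray
    fs: float
    lead_name: str = "ECG"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (single lead)")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.samples) / self.fs

    def replace_samples(self, samples: np.ndarray) -> "ECGRecord":
        return ECGRecord(self.record_id, samples, self.fs, self.lead_name)


@dataclass
class SyntheticECG:
    """Synthetic ECG with ground-truth R-peak positions.

    ``true_rpeaks`` are sample indices of the planted QRS apices;
    ``rr_truth`` are the interval durations (seconds) the waveform was
    built from, so ``diff(true_rpeaks) / fs`` matches ``rr_truth`` to
    within one sample quantum.
    """

    samples: np.ndarray
    fs: float
    true_rpeaks: np.ndarray
    rr_truth: np.ndarray
    record_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.true_rpeaks = np.asarray(self.true_rpeaks, dtype=np.int64)
        self.rr_truth = np.asarray(self.rr_truth, dtype=np.float64)
        if np.any(np.diff(self.true_rpeaks) <= 0):
            raise ValueError("true_rpeaks must be strictly increasing")

    def to_record(self) -> ECGRecord:
        return ECGRecord(self.record_id, self.samples, self.fs)


@dataclass(frozen=True)
class RhythmInterval:
    """Half-open-in-spirit rhythm span ``[start, end]`` in seconds."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"rhythm interval must have end > start, got ({self.start}, {self.end})"
            )
        if self.label not in RHYTHM_LABELS:
            raise ValueError(f"unknown rhythm label {self.label!r}; expected one of {RHYTHM_LABELS}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class RhythmTrack:
    """Sorted, non-overlapping rhythm annotation intervals for one record."""

    record_id: str
    intervals: list[RhythmInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError(
                    f"overlapping rhythm intervals: ({a.start},{a.end}) and ({b.start},{b.end})"
                )
        self.intervals = ivs

    @property
    def end_time(self) -> float:
        return self.intervals[-1].end if self.intervals else 0.0

    def spans(self, label: str) -> list[RhythmInterval]:
        return [iv for iv in self.intervals if iv.label == label]


@dataclass
class RPeakSeries:
    """Detected R-wave positions as sample indices at a sampling rate."""

    peak_indices: np.ndarray
    fs: float
    record_id: str = ""

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.peak_indices.size > 1 and np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_indices)

    @property
    def peak_times(self) -> np.ndarray:
        """Peak positions in seconds."""
        return self.peak_indices / self.fs


@dataclass
class RRSequence:
    """Ordered R-R interval durations in seconds.

    A record containing M+1 R-waves yields M intervals. ``beat_times``
    holds the time (seconds from record start) of each interval's
    terminating beat, used to relate windows back to rhythm annotations.
    """

    intervals: np.ndarray
    record_id: str = ""
    beat_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=np.float64)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if self.intervals.size and np.any(self.intervals <= 0):
            raise ValueError("all R-R intervals must be positive")
        if self.beat_times is None:
            self.beat_times = np.cumsum(self.intervals)
        else:
            self.beat_times = np.asarray(self.beat_times, dtype=np.float64)
            if len(self.beat_times) != len(self.intervals):
                raise ValueError("beat_times must have one entry per interval")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def m(self) -> int:
        """Number of intervals (M, for a record with M+1 R-waves)."""
        return len(self.intervals)


@dataclass
class RRWindow:
    """One classifier input: N consecutive R-R intervals plus provenance.

    ``time_to_onset`` is the gap (seconds) between the window's last beat
    and the next qualifying AF onset in the source record, or ``None`` for
    windows from normal-rhythm records.
    """

    values: np.ndarray
    label: str  # "PAFN" or "N"
    record_id: str = ""
    end_time: float = float("nan")
    time_to_onset: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.label not in ("PAFN", "N"):
            raise ValueError(f"label must be 'PAFN' or 'N', got {self.label!r}")
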