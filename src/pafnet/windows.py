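"""Record selection, labeling and sliding-window segmentation.

The positive class (PAFN) is beat data from a PAF subject at least 45
minutes away from any qualifying AF episode; the negative class (N) is
data from normal-sinus-rhythm subjects. Episode handling follows the AF
database extraction protocol:

* AF episodes of at least 5 minutes *qualify*: a 45-minute guard zone
  around them is excluded from PAFN content.
* AF spans shorter than 5 minutes do not count as episodes (no guard
  zone), but their own content is still never included.
* Atrial-flutter (AFL) and junctional-rhythm (J) spans are excluded from
  content outright.

Eligible time is cut into non-overlapping 30-minute slices; each slice's
R-R intervals are then segmented with a sliding window of N intervals and
step 1, yielding M - N + 1 windows from a slice of M intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RhythmTrack, RRSequence, RRWindow

__all__ = [
    "WindowConfig",
    "SelectionPolicy",
    "LabeledSlice",
    "WindowDataset",
    "slide",
    "select_pafn_segments",
    "build_dataset",
]

logger = logging.getLogger(__name__)

MIN_EPISODE_S = 300.0       # AF spans shorter than this do not qualify as episodes
GUARD_S = 45.0 * 60.0       # PAFN content must be this far from qualifying episodes
SLICE_S = 30.0 * 60.0       # selection produces 30-minute slices


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: N intervals per window, step per slide."""

    N: int = 100
    step: int = 1

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"window size N must be >= 2, got {self.N}")
        if self.step < 1:
            raise ValueError(f"step must be >= 1, got {self.step}")


@dataclass(frozen=True)
class SelectionPolicy:
    """Knobs of the PAFN extraction protocol (defaults follow the text)."""

    min_episode_s: float = MIN_EPISODE_S
    guard_s: float = GUARD_S
    slice_s: float = SLICE_S
    # if True, even sub-5-min AF spans trigger the 45-min guard zone
    guard_short_episodes: bool = False


@dataclass
class LabeledSlice:
    """A class-labeled contiguous R-R slice with provenance."""

    rr: RRSequence
    label: str
    start_time: float
    end_time: float
    next_onset_time: float | None = None  # next qualifying AF onset, seconds


def slide(rr: RRSequence, cfg: WindowConfig, label: str = "N",
          next_onset_time: float | None = None) -> list[RRWindow]:
    """Segment an R-R sequence into sliding windows.

    With step 1 a sequence of M intervals yields exactly M - N + 1
    windows; window k covers intervals [k, k+N) and inherits the time of
    its last beat as ``end_time``. A sequence shorter than N yields an
    empty list (logged, not an error — short records are skipped).
    """
    m, n = len(rr), cfg.N
    if m < n:
        logger.warning("sequence %s has M=%d < N=%d intervals; skipped", rr.record_id, m, n)
        return []
    starts = range(0, m - n + 1, cfg.step)
    out = []
    for k in starts:
        end_time = float(rr.beat_times[k + n - 1])
        tto = None if next_onset_time is None else next_onset_time - end_time
        out.append(RRWindow(values=rr.intervals[k : k + n], label=label,
                            record_id=rr.record_id, end_time=end_time, time_to_onset=tto))
    return out


def _excluded_spans(track: RhythmTrack, policy: SelectionPolicy) -> list[tuple[float, float]]:
    spans: list[tuple[float, float]] = []
    for iv in track.intervals:
        if iv.label == "AFIB":
            qualifies = iv.duration >= policy.min_episode_s or policy.guard_short_episodes
            if qualifies:
                spans.append((iv.start - policy.guard_s, iv.end + policy.guard_s))
            else:
                spans.append((iv.start, iv.end))  # content excluded, no guard zone
        elif iv.label in ("AFL", "J"):
            spans.append((iv.start, iv.end))
    return spans


def _allowed_intervals(total: float, excluded: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Complement of the union of excluded spans within [0, total]."""
    merged: list[list[float]] = []
    for s, e in sorted((max(0.0, s), min(total, e)) for s, e in excluded if e > 0 and s < total):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    allowed, cursor = [], 0.0
    for s, e in merged:
        if s > cursor:
            allowed.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < total:
        allowed.append((cursor, total))
    return allowed


def select_pafn_segments(
    track: RhythmTrack,
    rr: RRSequence,
    policy: SelectionPolicy | None = None,
) -> list[LabeledSlice]:
    """Extract PAFN-labeled 30-minute R-R slices from an annotated record.

    Every instant of a returned slice is at least 45 minutes from any
    qualifying AF episode, and never inside any AF/AFL/J span. Slices are
    non-overlapping, cut greedily from the start of each eligible stretch.
    Returns an empty (logged) list when no stretch is long enough.
    """
    policy = policy or SelectionPolicy()
    total = track.end_time
    allowed = _allowed_intervals(total, _excluded_spans(track, policy))

    onsets = sorted(iv.start for iv in track.spans("AFIB") if iv.duration >= policy.min_episode_s)
    slices: list[LabeledSlice] = []
    for a, b in allowed:
        start = a
        while start + policy.slice_s <= b + 1e-9:
            end = start + policy.slice_s
            # intervals fully inside the slice: the opening beat and the
            # terminating beat both within [start, end]
            mask = (rr.beat_times - rr.intervals >= start - 1e-9) & (rr.beat_times <= end + 1e-9)
            sub = RRSequence(intervals=rr.intervals[mask], record_id=rr.record_id,
                             beat_times=rr.beat_times[mask])
            next_onset = next((t for t in onsets if t >= end - 1e-9), None)
            slices.append(LabeledSlice(rr=sub, label="PAFN", start_time=start,
                                       end_time=end, next_onset_time=next_onset))
            start = end
    if not slices:
        logger.info("record %s: no eligible PAFN slice", track.record_id)
    return slices


@dataclass
class WindowDataset:
    """Materialized window set: values matrix, labels and provenance."""

    X: np.ndarray                      # (n_windows, N) float32
    y: np.ndarray                      # (n_windows,) int, 1 = PAFN, 0 = N
    meta: pd.DataFrame = field(repr=False, default=None)  # record_id, end_time, time_to_onset

    def __len__(self) -> int:
        return len(self.X)

    @property
    def class_counts(self) -> dict[str, int]:
        return {"PAFN": int((self.y == 1).sum()), "N": int((self.y == 0).sum())}

    def save(self, path) -> None:
        """Persist as compressed npz (values + labels + metadata columns)."""
        np.savez_compressed(
            path, X=self.X, y=self.y,
            record_id=self.meta["record_id"].to_numpy(dtype=object).astype(str),
            end_time=self.meta["end_time"].to_numpy(dtype=np.float64),
            time_to_onset=self.meta["time_to_onset"].to_numpy(dtype=np.float64),
        )

    @classmethod
    def load(cls, path) -> "WindowDataset":
        z = np.load(path, allow_pickle=False)
        meta = pd.DataFrame({
            "record_id": z["record_id"], "end_time": z["end_time"],
            "time_to_onset": z["time_to_onset"],
        })
        return cls(X=z["X"], y=z["y"], meta=meta)


def _windows_from_sequence(rr: RRSequence, cfg: WindowConfig, label: str,
                           next_onset: float | None) -> tuple[np.ndarray, pd.DataFrame]:
    m, n = len(rr), cfg.N
    if m < n:
        logger.warning("sequence %s has M=%d < N=%d intervals; skipped", rr.record_id, m, n)
        return np.empty((0, n), dtype=np.float32), pd.DataFrame(
            columns=["record_id", "end_time", "time_to_onset"])
    view = np.lib.stride_tricks.sliding_window_view(rr.intervals, n)[:: cfg.step]
    ends = rr.beat_times[n - 1 :][:: cfg.step][: len(view)]
    tto = np.full(len(view), np.nan) if next_onset is None else next_onset - ends
    meta = pd.DataFrame({"record_id": rr.record_id, "end_time": ends, "time_to_onset": tto})
    return view.astype(np.float32), meta


def build_dataset(
    paf_records: list[tuple[RRSequence, RhythmTrack | None]],
    normal_records: list[RRSequence],
    cfg: WindowConfig | None = None,
    policy: SelectionPolicy | None = None,
) -> WindowDataset:
    """Assemble the labeled window set for training.

    ``paf_records`` are (R-R sequence, rhythm track) pairs from PAF
    subjects; with a track, PAFN slices are selected by the extraction
    protocol, otherwise the whole sequence is taken as already-selected
    PAFN content. ``normal_records`` contribute N-labeled windows whole.
    Per-class counts are logged and available as ``class_counts``.
    """
    if not paf_records and not normal_records:
        raise ValueError("no records given: need at least one PAF or normal record")
    cfg = cfg or WindowConfig()
    xs: list[np.ndarray] = []
    metas: list[pd.DataFrame] = []
    labels: list[np.ndarray] = []

    for rr, track in paf_records:
        if track is None:
            pieces = [LabeledSlice(rr=rr, label="PAFN", start_time=0.0,
                                   end_time=float(rr.beat_times[-1]) if len(rr) else 0.0)]
        else:
            pieces = select_pafn_segments(track, rr, policy)
        for sl in pieces:
            x, meta = _windows_from_sequence(sl.rr, cfg, "PAFN", sl.next_onset_time)
            xs.append(x)
            metas.append(meta)
            labels.append(np.ones(len(x), dtype=np.int64))

    for rr in normal_records:
        x, meta = _windows_from_sequence(rr, cfg, "N", None)
        xs.append(x)
        metas.append(meta)
        labels.append(np.zeros(len(x), dtype=np.int64))

    X = np.concatenate(xs, axis=0) if xs else np.empty((0, cfg.N), dtype=np.float32)
    y = np.concatenate(labels) if labels else np.empty(0, dtype=np.int64)
    meta = (pd.concat(metas, ignore_index=True) if metas
            else pd.DataFrame(columns=["record_id", "end_time", "time_to_onset"]))
    ds = WindowDataset(X=X, y=y, meta=meta)
    logger.info("built dataset: %s windows (%s)", len(ds), ds.class_counts)
    return ds
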