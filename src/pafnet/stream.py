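"""Per-beat streaming prediction engine.

The engine keeps a ring buffer of the latest N R-R intervals. Each pushed
beat appends one interval (the difference to the previous beat time);
once N intervals have accumulated — i.e. from beat N+1 onward — every new
beat triggers one prediction on the current buffer. Memory is O(N)
regardless of stream length, and the emitted probability sequence is
identical to running the batch sliding-window pipeline over the full
record.
"""

from __future__ import annotations

import time
from collections import deque
from collections.abc import Callable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RRSequence

__all__ = ["RRStreamPredictor", "replay"]

#: A predictor maps a (n_windows, N) float array to positive-class probabilities.
WindowPredictor = Callable[[np.ndarray], np.ndarray]


@dataclass
class RRStreamPredictor:
    """Streaming state: ring buffer of intervals plus a window predictor.

    ``predict_fn`` is any callable returning positive-class probabilities
    for a batch of windows — a fitted classifier's sliced
    ``predict_proba`` or a fold-ensemble average.
    """

    predict_fn: WindowPredictor
    n_intervals: int
    _buffer: deque = field(init=False, repr=False)
    _last_time: float | None = field(init=False, default=None)
    beats_seen: int = field(init=False, default=0)
    predictions_emitted: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if self.n_intervals < 2:
            raise ValueError(f"n_intervals must be >= 2, got {self.n_intervals}")
        self._buffer = deque(maxlen=self.n_intervals)

    def push_beat(self, r_time: float) -> float | None:
        """Register one detected R-wave; return a probability when ready.

        The first N beats only fill the buffer: output starts at beat
        N+1. Beat times must be strictly increasing.
        """
        if self._last_time is not None:
            if r_time <= self._last_time:
                raise ValueError(
                    f"beat time {r_time} not after previous beat {self._last_time}")
            self._buffer.append(r_time - self._last_time)
        self._last_time = r_time
        self.beats_seen += 1
        if len(self._buffer) < self.n_intervals:
            return None
        window = np.asarray(self._buffer, dtype=np.float32)[None, :]
        p = float(self.predict_fn(window)[0])
        self.predictions_emitted += 1
        return p


def replay(rr: RRSequence, predict_fn: WindowPredictor, n_intervals: int,
           threshold: float = 0.5, first_beat_time: float = 0.0) -> pd.DataFrame:
    """Feed a recorded R-R sequence through the streaming engine beat by beat.

    Reconstructs beat times from the cumulative intervals and emits one row
    per prediction: beat index (1-based), beat time, probability, label at
    the threshold, and the per-beat compute latency in milliseconds
    (informational only — it depends on the host machine).
    """
    if len(rr) == 0:
        raise ValueError("cannot replay an empty R-R sequence")
    engine = RRStreamPredictor(predict_fn=predict_fn, n_intervals=n_intervals)
    beat_times = first_beat_time + np.concatenate([[0.0], np.cumsum(rr.intervals)])
    rows = []
    for i, t in enumerate(beat_times, start=1):
        t0 = time.perf_counter()
        p = engine.push_beat(float(t))
        dt_ms = (time.perf_counter() - t0) * 1e3
        if p is not None:
            rows.append({"beat_index": i, "r_time": float(t), "probability": p,
                         "label": int(p >= threshold), "latency_ms": dt_ms})
    return pd.DataFrame(rows)
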