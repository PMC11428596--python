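"""R-wave location and R-R interval derivation.

The detector is the classical threshold-on-difference scheme: first
difference -> squaring -> moving-window integration (150 ms) -> adaptive
amplitude threshold expressed as a fraction of a running peak estimate,
with a 200 ms refractory period, followed by local-maximum refinement on
the (filtered) input signal. Because the threshold is relative to the
signal's own running peak level, detection is invariant to global
amplitude scaling.

From M+1 detected R-waves the R-R sequence of M intervals follows as
``RR_i = (R_{i+1} - R_i) / fs`` in seconds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .containers import ECGRecord, RPeakSeries, RRSequence

__all__ = ["DetectorConfig", "detect_rpeaks", "derive_rr", "clean_rr"]

logger = logging.getLogger(__name__)

REFRACTORY_S = 0.2
INTEGRATION_S = 0.15


@dataclass(frozen=True)
class DetectorConfig:
    """Tunables of the threshold-difference detector."""

    threshold_frac: float = 0.3  # fraction of the running peak estimate
    refractory_s: float = REFRACTORY_S
    integration_s: float = INTEGRATION_S
    peak_memory: float = 0.125  # exponential update weight of the peak estimate


def detect_rpeaks(record: ECGRecord, config: DetectorConfig | None = None) -> RPeakSeries:
    """Locate R-waves on a preprocessed single-lead ECG.

    Returns sample indices of the refined peaks. A record shorter than
    2 s is rejected; an all-zero (or peak-free) signal yields an empty
    series.
    """
    cfg = config or DetectorConfig()
    x = record.samples
    fs = record.fs
    if len(x) < 2 * fs:
        raise ValueError(f"record of {len(x) / fs:.2f} s is shorter than the 2 s minimum")

    # difference -> squaring -> moving-window integration
    d = np.diff(x, prepend=x[0])
    sq = d * d
    win = max(1, int(round(cfg.integration_s * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refr = max(1, int(round(cfg.refractory_s * fs)))
    cand, _ = _signal.find_peaks(mwi, distance=refr)
    if cand.size == 0:
        return RPeakSeries(np.empty(0, dtype=np.int64), fs, record.record_id)

    # adaptive threshold: a fraction of an exponentially updated running
    # peak estimate, seeded from the first two seconds of integrated signal
    peak_est = float(np.max(mwi[: int(2 * fs)]))
    if peak_est <= 0:
        peak_est = float(np.max(mwi))
    if peak_est <= 0:
        return RPeakSeries(np.empty(0, dtype=np.int64), fs, record.record_id)
    accepted: list[int] = []
    for c in cand:
        if mwi[c] > cfg.threshold_frac * peak_est:
            accepted.append(int(c))
            peak_est = (1 - cfg.peak_memory) * peak_est + cfg.peak_memory * float(mwi[c])
    if not accepted:
        return RPeakSeries(np.empty(0, dtype=np.int64), fs, record.record_id)

    # refine each acceptance to the local maximum of the filtered signal
    half = win // 2 + 1
    refined: list[int] = []
    for c in accepted:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        p = lo + int(np.argmax(x[lo:hi]))
        if not refined or p - refined[-1] >= refr:
            refined.append(p)
        elif x[p] > x[refined[-1]]:
            refined[-1] = p
    return RPeakSeries(np.array(refined, dtype=np.int64), fs, record.record_id)


def derive_rr(peaks: RPeakSeries) -> RRSequence:
    """R-R intervals in seconds from consecutive R-peak sample indices.

    With M+1 peaks the result has M intervals; ``beat_times`` holds the
    time of each interval's terminating beat.
    """
    if len(peaks) < 2:
        raise ValueError(f"need at least 2 R-peaks to form an interval, got {len(peaks)}")
    intervals = np.diff(peaks.peak_indices) / peaks.fs
    beat_times = peaks.peak_indices[1:] / peaks.fs
    return RRSequence(intervals=intervals, record_id=peaks.record_id, beat_times=beat_times)


def clean_rr(rr: RRSequence, min_s: float = 0.3, max_s: float = 2.5) -> RRSequence:
    """Drop physiologically implausible intervals (detector glitches).

    Off the default pipeline path; apply explicitly when needed. Removals
    are logged, and a warning is raised when more than 10% of the record
    is dropped.
    """
    keep = (rr.intervals >= min_s) & (rr.intervals <= max_s)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("clean_rr dropped %d of %d intervals outside [%g, %g] s",
                    dropped, len(rr), min_s, max_s)
        if dropped > 0.1 * len(rr):
            warnings.warn(
                f"clean_rr removed {dropped}/{len(rr)} intervals (>10%); "
                "check detector settings for this record",
                stacklevel=2,
            )
    return RRSequence(intervals=rr.intervals[keep], record_id=rr.record_id,
                      beat_times=rr.beat_times[keep])
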