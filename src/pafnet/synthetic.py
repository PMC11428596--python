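"""Synthetic R-R sequences, ECG waveforms and rhythm-annotation tracks.

The generators provide ground truth for every downstream stage without any
database download. Two beat-to-beat regimes are emulated:

* ``NSR`` — normal sinus rhythm: Gaussian beat-to-beat jitter around a mean
  interval plus a slow sinusoidal modulation standing in for respiratory
  sinus arrhythmia.
* ``PAF_PRONE`` — the inter-episode rhythm of a paroxysmal-AF subject:
  the same base process with larger jitter and occasional premature beats,
  each modelled as a short interval followed by a compensatory pause.

The ECG generator places a fixed raised-cosine QRS-like deflection at the
cumulative R-times; it deliberately omits P/T waves and fibrillatory waves —
its purpose is a peak-detection oracle, not morphological realism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .containers import RhythmInterval, RhythmTrack, RRSequence, SyntheticECG

__all__ = [
    "RRGenConfig",
    "NSR_DEFAULTS",
    "PAF_PRONE_DEFAULTS",
    "generate_rr",
    "generate_ecg",
    "generate_rhythm_track",
]

logger = logging.getLogger(__name__)

CLIP_MIN_S = 0.3
CLIP_MAX_S = 2.5


@dataclass(frozen=True)
class RRGenConfig:
    """Parameters of the R-R interval generator.

    Parameters
    ----------
    class_label : {"NSR", "PAF_PRONE"}
        Rhythm regime to emulate.
    n_beats : int
        Number of intervals to generate.
    mean_rr : float
        Mean interval in seconds (0.3--2.0 s, i.e. 30--200 bpm).
    rr_sd : float
        Standard deviation of the Gaussian beat-to-beat jitter, seconds.
    resp_mod_depth : float
        Fractional depth of the sinusoidal respiratory modulation.
    resp_period : float
        Respiratory modulation period, in beats.
    premature_prob : float
        Per-beat probability of a premature beat (PAF_PRONE only).
    premature_scale : float
        Premature interval as a fraction (<1) of the local mean interval.
    compensatory_scale : float
        Compensatory pause as a multiple (>1) of the local mean interval.
    seed : int
        Seed for the generator; identical seed and config give identical
        output.
    """

    class_label: str = "NSR"
    n_beats: int = 1000
    mean_rr: float = 0.8
    rr_sd: float = 0.04
    resp_mod_depth: float = 0.03
    resp_period: float = 4.0
    premature_prob: float = 0.0
    premature_scale: float = 0.65
    compensatory_scale: float = 1.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in ("NSR", "PAF_PRONE"):
            raise ValueError(f"class_label must be 'NSR' or 'PAF_PRONE', got {self.class_label!r}")
        if self.n_beats < 1:
            raise ValueError(f"n_beats must be >= 1, got {self.n_beats}")
        if not (0.3 < self.mean_rr < 2.0):
            raise ValueError(f"mean_rr must lie in (0.3, 2.0) s, got {self.mean_rr}")
        if self.rr_sd < 0:
            raise ValueError(f"rr_sd must be >= 0, got {self.rr_sd}")
        if not (0.0 <= self.resp_mod_depth < 0.5):
            raise ValueError(f"resp_mod_depth must lie in [0, 0.5), got {self.resp_mod_depth}")
        if self.resp_period <= 0:
            raise ValueError(f"resp_period must be positive, got {self.resp_period}")
        if not (0.0 <= self.premature_prob <= 0.2):
            raise ValueError(f"premature_prob must lie in [0, 0.2], got {self.premature_prob}")
        if not (0.0 < self.premature_scale < 1.0):
            raise ValueError(f"premature_scale must lie in (0, 1), got {self.premature_scale}")
        if self.compensatory_scale <= 1.0:
            raise ValueError(f"compensatory_scale must be > 1, got {self.compensatory_scale}")


#: Default regimes. The two differ in jitter magnitude and in the presence
#: of premature beats, making them statistically separable while both
#: staying in a physiologically plausible band around 75 bpm.
NSR_DEFAULTS = RRGenConfig(class_label="NSR", mean_rr=0.8, rr_sd=0.04,
                           resp_mod_depth=0.03, resp_period=4.0, premature_prob=0.0)
PAF_PRONE_DEFAULTS = RRGenConfig(class_label="PAF_PRONE", mean_rr=0.8, rr_sd=0.08,
                                 resp_mod_depth=0.03, resp_period=4.0,
                                 premature_prob=0.05, premature_scale=0.65,
                                 compensatory_scale=1.35)


def default_config(class_label: str, **overrides) -> RRGenConfig:
    """Return the default config for a class, with optional field overrides."""
    base = NSR_DEFAULTS if class_label == "NSR" else PAF_PRONE_DEFAULTS
    if class_label not in ("NSR", "PAF_PRONE"):
        raise ValueError(f"unknown class_label {class_label!r}")
    return replace(base, **overrides)


def generate_rr(config: RRGenConfig, record_id: str = "synthetic") -> RRSequence:
    """Generate an R-R interval sequence under the given regime.

    The base process is ``mean_rr * (1 + resp_mod_depth * sin(2*pi*i/resp_period))``
    plus ``N(0, rr_sd)`` jitter. In the PAF_PRONE regime each beat is, with
    probability ``premature_prob``, replaced by a premature couplet: a short
    interval of ``premature_scale`` times the local mean followed by a
    compensatory pause of ``compensatory_scale`` times the local mean.
    All intervals are clipped to [0.3, 2.5] s.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_beats
    i = np.arange(n)
    base = config.mean_rr * (1.0 + config.resp_mod_depth * np.sin(2 * np.pi * i / config.resp_period))
    rr = base + rng.normal(0.0, config.rr_sd, size=n) if config.rr_sd > 0 else base.copy()

    if config.class_label == "PAF_PRONE" and config.premature_prob > 0:
        draws = rng.random(n)
        k = 0
        while k < n - 1:
            if draws[k] < config.premature_prob:
                # local mean over the recent past stabilises the couplet
                # amplitude against the respiratory modulation
                lo = max(0, k - 8)
                local_mean = float(np.mean(rr[lo:k])) if k > lo else config.mean_rr
                rr[k] = config.premature_scale * local_mean
                rr[k + 1] = config.compensatory_scale * local_mean
                k += 2  # the compensatory beat cannot itself be premature
            else:
                k += 1

    rr = np.clip(rr, CLIP_MIN_S, CLIP_MAX_S)
    return RRSequence(intervals=rr, record_id=record_id)


# 30 ms wide raised-cosine deflection: the narrowest feature a QRS-complex
# detector must survive, with an unambiguous apex.
QRS_WIDTH_S = 0.030
QRS_AMPLITUDE = 1.0
WANDER_FREQ_HZ = 0.25


def _qrs_template(fs: float) -> np.ndarray:
    half = max(1, int(round(QRS_WIDTH_S * fs / 2)))
    t = np.arange(-half, half + 1)
    return QRS_AMPLITUDE * 0.5 * (1 + np.cos(np.pi * t / half))


def generate_ecg(
    rr: RRSequence,
    fs: float = 128.0,
    noise_sd: float = 0.0,
    wander_amp: float = 0.0,
    seed: int = 0,
    lead_pad_s: float = 0.5,
) -> SyntheticECG:
    """Render an R-R sequence as a synthetic single-lead ECG.

    A fixed raised-cosine QRS-like template is placed at each cumulative
    R-time; optional sinusoidal baseline wander (0.25 Hz) and white Gaussian
    noise are added. Returns the exact sample indices of the planted apices.
    """
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz, got {fs}")
    if len(rr) == 0:
        raise ValueError("cannot render an empty R-R sequence")
    rng = np.random.default_rng(seed)

    r_times = lead_pad_s + np.concatenate([[0.0], np.cumsum(rr.intervals)])
    peak_idx = np.round(r_times * fs).astype(np.int64)
    n_samples = int(peak_idx[-1] + round(lead_pad_s * fs)) + 1
    x = np.zeros(n_samples)

    tpl = _qrs_template(fs)
    half = len(tpl) // 2
    for p in peak_idx:
        lo, hi = p - half, p + half + 1
        s0, s1 = max(lo, 0), min(hi, n_samples)
        x[s0:s1] += tpl[s0 - lo : len(tpl) - (hi - s1)]

    if wander_amp > 0:
        t = np.arange(n_samples) / fs
        x += wander_amp * np.sin(2 * np.pi * WANDER_FREQ_HZ * t + rng.uniform(0, 2 * np.pi))
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n_samples)

    return SyntheticECG(samples=x, fs=fs, true_rpeaks=peak_idx,
                        rr_truth=rr.intervals.copy(), record_id=rr.record_id)


def generate_rhythm_track(
    episodes: list[tuple[float, float]] | None,
    total_duration: float,
    record_id: str = "synthetic",
    episode_label: str = "AFIB",
    extra_labels: list[tuple[float, float, str]] | None = None,
) -> RhythmTrack:
    """Build a rhythm track with the given AF episodes and N-labeled gaps.

    ``episodes`` are (start, end) spans in seconds labeled ``episode_label``;
    ``extra_labels`` adds spans of other rhythms (e.g. AFL, J). All spans
    must be non-overlapping and inside [0, total_duration]; remaining time
    is labeled N (normal sinus rhythm).
    """
    if total_duration <= 0:
        raise ValueError(f"total_duration must be positive, got {total_duration}")
    spans: list[tuple[float, float, str]] = [(s, e, episode_label) for s, e in (episodes or [])]
    spans += list(extra_labels or [])
    for s, e, lab in spans:
        if not (0 <= s < e <= total_duration):
            raise ValueError(f"span ({s}, {e}, {lab}) outside [0, {total_duration}]")
    spans.sort()
    for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping spans ({s1},{e1},{l1}) and ({s2},{e2},{l2})")

    intervals: list[RhythmInterval] = []
    cursor = 0.0
    for s, e, lab in spans:
        if s > cursor:
            intervals.append(RhythmInterval(cursor, s, "N"))
        intervals.append(RhythmInterval(s, e, lab))
        cursor = e
    if cursor < total_duration:
        intervals.append(RhythmInterval(cursor, total_duration, "N"))
    return RhythmTrack(record_id=record_id, intervals=intervals)
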