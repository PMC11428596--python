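"""Reading and writing ECG records, rhythm annotations and R-R sequences.

Records use the PhysioNet waveform-database layout: a text ``.hea`` header
plus a format-16 (little-endian 16-bit) ``.dat`` signal file. Only that
signal format is supported — it is the one the public AF databases use.
Rhythm annotations are stored as a tab-separated text file (``.ann``)
mirroring the ``rdann`` text representation: one rhythm-change marker per
line with its sample index and an aux string like ``(AFIB``.

R-R interval sequences travel as plain CSV, one interval in seconds per
line, optionally with a second column carrying the terminating beat time.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .containers import ECGRecord, RhythmTrack, RRSequence, SyntheticECG

__all__ = [
    "FormatError",
    "read_record",
    "write_record",
    "read_rhythm_annotations",
    "write_rhythm_annotations",
    "read_rr_csv",
    "write_rr_csv",
]

logger = logging.getLogger(__name__)

DEFAULT_ADC_GAIN = 200.0  # ADC units per millivolt, the common AFDB setting
_AUX_TO_LABEL = {"(N": "N", "(NSR": "N", "(AFIB": "AFIB", "(AFL": "AFL", "(J": "J"}
_LABEL_TO_AUX = {"N": "(N", "AFIB": "(AFIB", "AFL": "(AFL", "J": "(J"}


class FormatError(ValueError):
    """Raised when a file does not follow the supported format dialect."""


def _parse_header(hea_path: Path) -> dict:
    lines = [ln.split("#", 1)[0].strip() for ln in hea_path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise FormatError(f"empty header file: {hea_path}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed header record line in {hea_path}: {lines[0]!r}")
    record_id, n_sig, fs, n_samples = head[0], int(head[1]), float(head[2].split("/")[0]), int(head[3])
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise FormatError(f"malformed signal line in {hea_path}: {ln!r}")
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        if fmt != "16":
            raise FormatError(f"unsupported signal format {tok[1]!r} in {hea_path}; only format 16 is supported")
        gain = DEFAULT_ADC_GAIN
        baseline = 0
        if len(tok) >= 3:
            gain_tok = tok[2]
            if "(" in gain_tok:
                gain_part, base_part = gain_tok.split("(", 1)
                baseline = int(base_part.split("/")[0].rstrip(")"))
                gain_tok = gain_part
            gain = float(gain_tok.split("/")[0]) or DEFAULT_ADC_GAIN
        name = tok[-1] if len(tok) >= 9 else f"lead{len(signals)}"
        signals.append({"file": tok[0], "gain": gain, "baseline": baseline, "name": name})
    return {"record_id": record_id, "n_sig": n_sig, "fs": fs, "n_samples": n_samples, "signals": signals}


def read_record(path: str | Path, lead_index: int = 0) -> ECGRecord:
    """Read one lead of a waveform-database record.

    ``path`` is the record path without extension (``dir/rec`` for
    ``dir/rec.hea`` + ``dir/rec.dat``). Samples are returned in physical
    units (millivolts), ``(raw - baseline) / gain``; sampling frequency is
    taken from the header. Never resamples or rescales beyond that.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"header file not found: {hea}")
    hdr = _parse_header(hea)
    if not (0 <= lead_index < hdr["n_sig"]):
        raise IndexError(f"lead_index {lead_index} out of range for {hdr['n_sig']} signal(s)")
    sig = hdr["signals"][lead_index]
    dat = path.parent / sig["file"]
    if not dat.exists():
        raise FileNotFoundError(f"signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    n_sig = hdr["n_sig"]
    if raw.size < hdr["n_samples"] * n_sig:
        raise FormatError(
            f"signal file {dat} holds {raw.size} samples, header promises {hdr['n_samples'] * n_sig}"
        )
    lead = raw[: hdr["n_samples"] * n_sig].reshape(-1, n_sig)[:, lead_index]
    physical = (lead.astype(np.float64) - sig["baseline"]) / sig["gain"]
    return ECGRecord(record_id=hdr["record_id"], samples=physical, fs=hdr["fs"], lead_name=sig["name"])


def write_record(
    record: ECGRecord | SyntheticECG,
    directory: str | Path,
    adc_gain: float = DEFAULT_ADC_GAIN,
) -> Path:
    """Write a record as ``<record_id>.hea`` + format-16 ``<record_id>.dat``.

    Samples are quantised as ``round(sample * adc_gain)`` into int16; the
    quantisation step is ``1/adc_gain`` mV. Returns the record path
    (without extension).
    """
    if isinstance(record, SyntheticECG):
        record = record.to_record()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    raw = np.round(record.samples * adc_gain)
    if np.any(np.abs(raw) > 32767):
        raise ValueError("samples overflow int16 at this ADC gain; lower adc_gain")
    raw = raw.astype("<i2")
    base = directory / record.record_id
    fs_txt = f"{record.fs:g}"
    header = (
        f"{record.record_id} 1 {fs_txt} {len(raw)}\n"
        f"{record.record_id}.dat 16 {adc_gain:g}(0)/mV 16 0 {raw[0] if raw.size else 0} 0 0 {record.lead_name}\n"
    )
    base.with_suffix(".hea").write_text(header)
    raw.tofile(base.with_suffix(".dat"))
    return base


def write_rhythm_annotations(track: RhythmTrack, path: str | Path, fs: float) -> Path:
    """Write rhythm-change markers as rdann-style text (sample, '+', aux)."""
    path = Path(path)
    lines = [f"{int(round(iv.start * fs))}\t+\t{_LABEL_TO_AUX[iv.label]}" for iv in track.intervals]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_rhythm_annotations(path: str | Path, duration: float, fs: float,
                            record_id: str = "") -> RhythmTrack:
    """Read rhythm-change markers and convert them to closed intervals.

    Each ``+`` marker opens a rhythm span that runs until the next marker;
    the last span ends at ``duration``. Markers beyond the record duration
    are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    changes: list[tuple[float, str]] = []
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        tok = ln.split()
        if len(tok) < 3 or tok[1] != "+":
            raise FormatError(f"{path}:{lineno}: expected '<sample>\\t+\\t(<rhythm>', got {ln!r}")
        try:
            t = int(tok[0]) / fs
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer sample index {tok[0]!r}") from exc
        aux = tok[2]
        if aux not in _AUX_TO_LABEL:
            raise FormatError(f"{path}:{lineno}: unknown rhythm aux {aux!r}")
        if t > duration + 1e-9:
            raise ValueError(f"{path}:{lineno}: annotation at {t:.3f} s beyond record duration {duration:.3f} s")
        changes.append((t, _AUX_TO_LABEL[aux]))
    from .synthetic import generate_rhythm_track  # local import avoids cycle at module load

    if not changes:
        return generate_rhythm_track(None, duration, record_id=record_id or path.stem)
    track_id = record_id or path.stem
    intervals = []
    from .containers import RhythmInterval

    for (t0, lab), (t1, _) in zip(changes, changes[1:]):
        if t1 > t0:
            intervals.append(RhythmInterval(t0, t1, lab))
    if duration > changes[-1][0]:
        intervals.append(RhythmInterval(changes[-1][0], duration, changes[-1][1]))
    if changes[0][0] > 0:
        intervals.insert(0, RhythmInterval(0.0, changes[0][0], "N"))
    return RhythmTrack(record_id=track_id, intervals=intervals)


def write_rr_csv(rr: RRSequence, path: str | Path, with_beat_times: bool = False) -> Path:
    """Write an R-R sequence as CSV, one interval (seconds) per line."""
    path = Path(path)
    if with_beat_times:
        lines = [f"{iv:.9f},{bt:.9f}" for iv, bt in zip(rr.intervals, rr.beat_times)]
    else:
        lines = [f"{iv:.9f}" for iv in rr.intervals]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_rr_csv(path: str | Path, record_id: str = "") -> RRSequence:
    """Read an R-R sequence written by :func:`write_rr_csv`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"R-R CSV not found: {path}")
    intervals: list[float] = []
    beat_times: list[float] = []
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln:
            continue
        cols = ln.split(",")
        try:
            intervals.append(float(cols[0]))
            if len(cols) > 1:
                beat_times.append(float(cols[1]))
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value on line {lineno}: {ln!r}") from exc
    return RRSequence(
        intervals=np.array(intervals, dtype=np.float64),
        record_id=record_id or path.stem,
        beat_times=np.array(beat_times) if beat_times else None,
    )
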