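"""Readers and writers for the formats the pipeline touches.

Real Physionet apnea records (WFDB header/signal pairs with minute-wise
apnea annotations) and synthetic fixtures flow through the same
:class:`RRSeries` container.  The WFDB support here is deliberately
minimal — text ``.hea`` headers, format-16 ``.dat`` signals, and the
minute-wise apnea annotation dialect (either MIT binary annotations or a
plain-text ``A``/``N`` file) — which covers the apnea databases this
package targets.

Minute indexing is 0-based and half-open: minute ``m`` covers the
interval ``[60*m, 60*(m+1))`` seconds from record start.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError

APNEA = "apnea"
NON_APNEA = "non_apnea"

#: Physiologic plausibility gate for beat-to-beat intervals (ms).
RR_MIN_MS = 300.0
RR_MAX_MS = 2000.0


@dataclass
class RRSeries:
    """Timestamped beat-to-beat (RR) intervals with optional minute labels.

    Parameters
    ----------
    beat_times
        Beat occurrence times, seconds from record start, strictly
        increasing.
    intervals
        Milliseconds; ``intervals[i] = 1000 * (beat_times[i+1] - beat_times[i])``.
    record_id
        Opaque identifier.
    annotations
        Optional per-minute labels, values :data:`APNEA` / :data:`NON_APNEA`;
        length must equal ``duration_min``.
    duration_min
        Record duration in whole minutes.  Defaults to
        ``ceil(beat_times[-1] / 60)``.
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    record_id: str = "unnamed"
    annotations: list[str] | None = None
    duration_min: int = field(default=-1)

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if len(self.intervals) != len(self.beat_times) - 1:
            raise FormatError(
                f"expected {len(self.beat_times) - 1} intervals, "
                f"got {len(self.intervals)}"
            )
        if np.any(np.diff(self.beat_times) <= 0):
            raise FormatError("beat times must be strictly increasing")
        if np.any(self.intervals <= 0):
            raise FormatError("all RR intervals must be positive")
        if self.duration_min < 0:
            self.duration_min = int(np.ceil(self.beat_times[-1] / 60.0)) if len(self.beat_times) else 0
        if self.annotations is not None and len(self.annotations) != self.duration_min:
            raise AlignmentError(
                f"{len(self.annotations)} annotations for a "
                f"{self.duration_min}-minute record"
            )

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)

    def minute_of_beat(self) -> np.ndarray:
        """0-based minute index of each beat (half-open minute windows)."""
        return np.floor(self.beat_times / 60.0).astype(int)

    def beats_in_minute(self, minute: int) -> np.ndarray:
        """Indices of beats with ``60*minute <= t < 60*(minute+1)``."""
        t = self.beat_times
        return np.nonzero((t >= 60.0 * minute) & (t < 60.0 * (minute + 1)))[0]


def gate_rr_outliers(series: RRSeries, lo_ms: float = RR_MIN_MS, hi_ms: float = RR_MAX_MS) -> RRSeries:
    """Remove physiologically implausible intervals, bridging the gap.

    Intervals shorter than ``lo_ms`` are treated as ectopic/spurious
    detections: the later beat is dropped and adjacent intervals merged.
    Intervals longer than ``hi_ms`` are treated as missed beats: beat
    times are interpolated evenly across the gap so that the bridged
    sub-intervals approximate the local median RR.
    """
    times = list(series.beat_times)
    i = 1
    while i < len(times):
        rr = (times[i] - times[i - 1]) * 1000.0
        if rr < lo_ms and len(times) > 2:
            del times[i]
        else:
            i += 1
    out: list[float] = [times[0]]
    rrs = np.diff(times) * 1000.0
    local_median = float(np.median(rrs[rrs <= hi_ms])) if np.any(rrs <= hi_ms) else 1000.0
    for j in range(1, len(times)):
        gap_ms = (times[j] - times[j - 1]) * 1000.0
        if gap_ms > hi_ms:
            n_insert = int(round(gap_ms / local_median)) - 1
            if n_insert > 0:
                step = (times[j] - times[j - 1]) / (n_insert + 1)
                out.extend(times[j - 1] + step * k for k in range(1, n_insert + 1))
        out.append(times[j])
    times_arr = np.asarray(out)
    return replace(
        series,
        beat_times=times_arr,
        intervals=np.diff(times_arr) * 1000.0,
    )


# ---------------------------------------------------------------------------
# RR CSV dialect: header "time_s,rr_ms", one row per interval, time_s the
# onset beat of the interval; sidecar "<stem>.labels.csv" with "minute,label".
# ---------------------------------------------------------------------------

def write_rr_csv(series: RRSeries, path: str | os.PathLike) -> None:
    """Write a series as ``time_s,rr_ms`` CSV plus a label sidecar."""
    path = os.fspath(path)
    df = pd.DataFrame(
        {"time_s": series.beat_times[:-1], "rr_ms": series.intervals}
    )
    df.to_csv(path, index=False)
    if series.annotations is not None:
        side = _labels_sidecar_path(path)
        pd.DataFrame(
            {"minute": np.arange(series.duration_min), "label": series.annotations}
        ).to_csv(side, index=False)


def read_rr_csv(path: str | os.PathLike) -> RRSeries:
    """Read the ``time_s,rr_ms`` dialect written by :func:`write_rr_csv`."""
    path = os.fspath(path)
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "rr_ms"]:
        raise FormatError(f"expected header 'time_s,rr_ms', got {list(df.columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    rr = df["rr_ms"].to_numpy(dtype=float)
    if np.any(rr <= 0):
        raise FormatError("negative or zero rr_ms value")
    if np.any(np.diff(t) <= 0):
        raise FormatError("time_s column is not strictly increasing")
    beat_times = np.concatenate([t, [t[-1] + rr[-1] / 1000.0]])
    annotations = None
    side = _labels_sidecar_path(path)
    if os.path.exists(side):
        lab = pd.read_csv(side)
        annotations = list(lab.sort_values("minute")["label"])
    record_id = os.path.splitext(os.path.basename(path))[0]
    return RRSeries(beat_times, np.diff(beat_times) * 1000.0, record_id=record_id,
                    annotations=annotations,
                    duration_min=len(annotations) if annotations is not None else -1)


def _labels_sidecar_path(path: str) -> str:
    stem, _ = os.path.splitext(path)
    return stem + ".labels.csv"


# ---------------------------------------------------------------------------
# Minimal WFDB support (format-16 signals only)
# ---------------------------------------------------------------------------

@dataclass
class _WfdbHeader:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    dat_files: list[str]
    formats: list[int]
    gains: list[float]
    baselines: list[int]


def _read_wfdb_header(hea_path: str) -> _WfdbHeader:
    if not os.path.exists(hea_path):
        raise FormatError(f"missing WFDB header {hea_path}")
    lines = []
    with open(hea_path) as fh:
        for raw in fh:
            raw = raw.strip()
            if raw and not raw.startswith("#"):
                lines.append(raw)
    if not lines:
        raise FormatError(f"empty WFDB header {hea_path}")
    head = lines[0].split()
    try:
        record_name = head[0].split("/")[0]
        n_sig = int(head[1])
        fs = float(head[2]) if len(head) > 2 else 250.0
        n_samples = int(head[3]) if len(head) > 3 else 0
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed WFDB record line: {lines[0]!r}") from exc
    dat_files, formats, gains, baselines = [], [], [], []
    for line in lines[1:1 + n_sig]:
        parts = line.split()
        try:
            dat_files.append(parts[0])
            fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
            formats.append(fmt)
            gain_spec = parts[2] if len(parts) > 2 else "200"
            gain_field = gain_spec.split("/")[0]
            if "(" in gain_field:
                gain, base = gain_field.rstrip(")").split("(")
            else:
                gain, base = gain_field, "0"
            gains.append(float(gain) if float(gain) != 0 else 200.0)
            baselines.append(int(float(base)))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"malformed WFDB signal line: {line!r}") from exc
    if len(dat_files) < n_sig:
        raise FormatError(f"header declares {n_sig} signals, lists {len(dat_files)}")
    return _WfdbHeader(record_name, n_sig, fs, n_samples, dat_files, formats, gains, baselines)


def _read_wfdb_signal(base_dir: str, header: _WfdbHeader, channel: int) -> np.ndarray:
    """Physical units of one channel; format 16 (little-endian int16) only."""
    if not (0 <= channel < header.n_sig):
        raise FormatError(f"channel {channel} out of range (n_sig={header.n_sig})")
    if header.formats[channel] != 16:
        raise FormatError(f"unsupported WFDB signal format {header.formats[channel]}")
    dat_path = os.path.join(base_dir, header.dat_files[channel])
    if not os.path.exists(dat_path):
        raise FormatError(f"missing WFDB signal file {dat_path}")
    # all channels sharing one .dat file are sample-interleaved
    group = [i for i, f in enumerate(header.dat_files) if f == header.dat_files[channel]]
    try:
        raw = np.fromfile(dat_path, dtype="<i2")
    except OSError as exc:
        raise FormatError(f"unreadable samples in {dat_path}") from exc
    stride = len(group)
    pos = group.index(channel)
    adc = raw[pos::stride]
    if header.n_samples and len(adc) < header.n_samples:
        raise FormatError(
            f"{dat_path} holds {len(adc)} samples, header declares {header.n_samples}"
        )
    if header.n_samples:
        adc = adc[: header.n_samples]
    return (adc.astype(float) - header.baselines[channel]) / header.gains[channel]


# MIT binary annotation codes used by the apnea databases
_MIT_NORMAL = 1   # rendered 'N'
_MIT_APNEA = 8    # rendered 'A' in the Apnea-ECG .apn files


def _read_apnea_annotations(path: str) -> list[str]:
    """Minute-wise A/N labels from a plain-text or MIT binary annotation file."""
    with open(path, "rb") as fh:
        blob = fh.read()
    try:
        text = blob.decode("ascii")
        if set(text.split()) <= {"A", "N"} and text.strip():
            return [APNEA if s == "A" else NON_APNEA for s in text.split()]
    except UnicodeDecodeError:
        pass
    return _parse_mit_annotations(blob)


def _parse_mit_annotations(blob: bytes) -> list[str]:
    """Decode MIT-format annotation pairs into minute-ordered A/N labels."""
    labels: list[str] = []
    i = 0
    n = len(blob)
    while i + 1 < n:
        b0, b1 = blob[i], blob[i + 1]
        i += 2
        code = b1 >> 2
        if code == 0 and b0 == 0:
            break  # end of annotation stream
        if code == 59:  # SKIP: 4-byte interval follows
            i += 4
        elif code == 63:  # AUX: length in time field, padded to even
            length = ((b1 & 3) << 8) + b0
            i += length + (length & 1)
        elif code in (60, 61, 62):  # NUM / SUB / CHN modifiers
            continue
        elif code == _MIT_APNEA:
            labels.append(APNEA)
        elif code == _MIT_NORMAL:
            labels.append(NON_APNEA)
        else:
            continue  # other beat/rhythm codes are not minute labels
    if not labels:
        raise FormatError("no minute-wise apnea annotations decoded")
    return labels


def events_to_minute_labels(events: list[tuple[float, float]], duration_min: int) -> list[str]:
    """Convert UCD-style (start_s, duration_s) event lists to minute labels.

    A minute is apneic iff any event overlaps its half-open window.
    """
    labels = [NON_APNEA] * duration_min
    for start, dur in events:
        first = int(np.floor(start / 60.0))
        last = int(np.floor((start + dur) / 60.0 - 1e-9))
        for m in range(max(first, 0), min(last, duration_min - 1) + 1):
            labels[m] = APNEA
    return labels


def detect_qrs(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Pan–Tompkins-style QRS detection; returns beat times in seconds.

    Band-pass (5–15 Hz) → derivative → squaring → 150 ms moving-window
    integration → adaptive threshold with a 200 ms refractory period.
    """
    from scipy import signal as sps

    nyq = fs / 2.0
    hi = min(15.0, 0.9 * nyq)
    b, a = sps.butter(2, [5.0 / nyq, hi / nyq], btype="band")
    filtered = sps.filtfilt(b, a, ecg)
    deriv = np.gradient(filtered)
    squared = deriv ** 2
    win = max(int(0.150 * fs), 1)
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    threshold = 0.3 * np.max(integrated[: int(min(len(integrated), 10 * fs))])
    refractory = int(0.200 * fs)
    peaks, _ = sps.find_peaks(integrated, height=threshold, distance=refractory)
    if len(peaks) == 0:
        return np.empty(0)
    # adapt: re-threshold against the running median of accepted peak heights
    heights = integrated[peaks]
    adaptive = 0.3 * np.median(heights)
    peaks = peaks[heights >= adaptive]
    # refine each peak to the local maximum of |filtered| nearby
    half = int(0.075 * fs)
    refined = []
    for p in peaks:
        lo, hi_i = max(p - half, 0), min(p + half + 1, len(filtered))
        refined.append(lo + int(np.argmax(np.abs(filtered[lo:hi_i]))))
    return np.unique(refined) / fs


def read_wfdb_apnea_record(path: str | os.PathLike, channel: int = 0,
                           annotation_path: str | os.PathLike | None = None,
                           gate_outliers: bool = True) -> RRSeries:
    """Read a WFDB record (+ optional apnea annotations) into an RR series.

    Parameters
    ----------
    path
        Record path without extension (``.hea``/``.dat`` appended), or
        the ``.hea`` path itself.
    channel
        ECG channel index.
    annotation_path
        Apnea annotation file; defaults to ``<record>.apn`` when present.
    gate_outliers
        Apply the [300, 2000] ms plausibility gate after QRS detection.
    """
    path = os.fspath(path)
    if path.endswith(".hea"):
        path = path[:-4]
    base_dir = os.path.dirname(path) or "."
    header = _read_wfdb_header(path + ".hea")
    ecg = _read_wfdb_signal(base_dir, header, channel)
    beat_times = detect_qrs(ecg, header.fs)
    if len(beat_times) < 2:
        raise FormatError(f"QRS detection found {len(beat_times)} beats in {path}")
    duration_s = (header.n_samples or len(ecg)) / header.fs
    duration_min = int(np.floor(duration_s / 60.0))

    annotations = None
    if annotation_path is None and os.path.exists(path + ".apn"):
        annotation_path = path + ".apn"
    if annotation_path is not None:
        annotations = _read_apnea_annotations(os.fspath(annotation_path))
        if abs(len(annotations) - duration_min) > 1:
            raise AlignmentError(
                f"{len(annotations)} annotations for a {duration_min}-minute signal"
            )
        if len(annotations) != duration_min:
            warnings.warn(
                f"trimming/padding annotations from {len(annotations)} to "
                f"{duration_min} minutes", stacklevel=2)
            annotations = (annotations + [NON_APNEA])[:duration_min]

    series = RRSeries(beat_times, np.diff(beat_times) * 1000.0,
                      record_id=header.record_name,
                      annotations=annotations, duration_min=duration_min)
    if gate_outliers:
        series = gate_rr_outliers(series)
        if annotations is not None:
            series = replace(series, annotations=annotations, duration_min=duration_min)
    return series
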