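"""EDF recording and seizure-annotation I/O.

The canonical on-disk formats are EDF (16-bit, 1 s data records) for signals
and a ``session,onset_s,offset_s`` CSV for seizure annotations.  A small
adapter parses CHB-MIT style ``*-summary.txt`` files into the same interval
type.  No EDF library is assumed: the reader/writer below implements the
subset of the EDF specification this package emits (integer sampling rates,
microvolt physical units, equal-length records).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "SeizureInterval",
    "IntegrityError",
    "read_recording",
    "write_recording",
    "parse_annotations",
    "write_annotations",
    "parse_chbmit_summary",
    "merge_intervals",
    "intersect_channels",
    "resample_recording",
]


class IntegrityError(RuntimeError):
    """Raised for unreadable or truncated EDF files (callers may skip + log)."""


@dataclass
class Recording:
    """One subject-session of multichannel scalp EEG.

    ``signal`` is ``[n_channels, n_samples]`` in microvolts; ``channel_labels``
    are montage names (e.g. ``"FT9-FT10"``) in a fixed order.
    """

    subject_id: str
    session_id: str
    channel_labels: list[str]
    sampling_rate_hz: float
    signal: np.ndarray
    line_noise_hz: int = 60

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D [n_channels, n_samples]")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows != "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.line_noise_hz not in (50, 60):
            raise ValueError("line_noise_hz must be 50 or 60")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def copy_with(self, **kwargs) -> "Recording":
        if "signal" not in kwargs:
            kwargs["signal"] = self.signal.copy()
        return replace(self, **kwargs)


@dataclass(frozen=True, order=True)
class SeizureInterval:
    """Half-open annotated seizure interval [onset_s, offset_s) in seconds."""

    session_id: str = field(compare=False)
    onset_s: float = 0.0
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be non-negative")
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"offset ({self.offset_s}) must exceed onset ({self.onset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


# ---------------------------------------------------------------------------
# EDF reading / writing
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as a 16-bit EDF file with 1 s data records.

    Physical units are microvolts; the sampling rate must be a positive
    integer (EDF stores integer samples per record).  The tail is zero-padded
    to a whole number of records.
    """
    path = Path(path)
    fs = rec.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    ns = rec.n_channels
    n_records = math.ceil(rec.n_samples / fs)
    padded = np.zeros((ns, n_records * fs), dtype=np.float64)
    padded[:, : rec.n_samples] = rec.signal

    pmins, pmaxs = [], []
    digital = np.empty_like(padded, dtype=np.int16)
    for c in range(ns):
        amp = float(np.max(np.abs(padded[c]))) if padded[c].size else 0.0
        amp = max(amp * 1.001, 1.0)  # symmetric range, never zero-width
        pmin, pmax = -amp, amp
        scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)
        dig = np.round((padded[c] - pmin) * scale) + _EDF_DIG_MIN
        digital[c] = np.clip(dig, _EDF_DIG_MIN, _EDF_DIG_MAX).astype(np.int16)
        pmins.append(pmin)
        pmaxs.append(pmax)

    header_bytes = 256 + ns * 256
    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii(rec.subject_id, 80))
        fh.write(_ascii(rec.session_id, 80))
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(header_bytes, 8))
        fh.write(_ascii(f"line={rec.line_noise_hz}", 44))
        fh.write(_ascii(n_records, 8))
        fh.write(_ascii(1, 8))  # record duration, seconds
        fh.write(_ascii(ns, 4))
        for label in rec.channel_labels:
            fh.write(_ascii(label, 16))
        fh.write(_ascii("", 80) * ns)  # transducer
        fh.write(_ascii("uV", 8) * ns)
        for pmin in pmins:
            fh.write(_ascii(f"{pmin:.6g}"[:8], 8))
        for pmax in pmaxs:
            fh.write(_ascii(f"{pmax:.6g}"[:8], 8))
        fh.write(_ascii(_EDF_DIG_MIN, 8) * ns)
        fh.write(_ascii(_EDF_DIG_MAX, 8) * ns)
        fh.write(_ascii("", 80) * ns)  # prefiltering
        fh.write(_ascii(fs, 8) * ns)
        fh.write(_ascii("", 32) * ns)
        # data: records of ns consecutive channel blocks, int16 little-endian
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.astype("<i2").tobytes())
    return path


def read_recording(
    path: str | Path,
    line_noise_hz: int | None = None,
    strict: bool = False,
    expected_rate_hz: float = 256.0,
    drop_duplicate_labels: bool = False,
    unit_scale: float = 1.0,
) -> Recording:
    """Read an EDF file into a Recording (signal in microvolts).

    ``strict`` additionally verifies the expected sampling rate and that the
    file length matches the header (duration continuity); violations raise
    ``ValueError`` / ``IntegrityError``.  ``drop_duplicate_labels`` drops
    later exact-duplicate channel labels with a log entry instead of raising.
    ``unit_scale`` multiplies physical values (for files not stored in uV).
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:  # pragma: no cover
        raise IntegrityError(f"unreadable EDF file {path}: {exc}") from exc
    if len(raw) < 256:
        raise IntegrityError(f"{path}: truncated EDF header")

    def fld(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    reserved = fld(192, 44)
    n_records = int(fld(236, 8))
    record_dur = float(fld(244, 8))
    ns = int(fld(252, 4))
    hdr = 256 + ns * 256
    if len(raw) < hdr:
        raise IntegrityError(f"{path}: truncated EDF signal headers")

    def sig_fld(block_off: int, width: int, i: int) -> str:
        off = 256 + block_off * ns + width * i
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    labels = [sig_fld(0, 16, i) for i in range(ns)]
    pmin = [float(sig_fld(16 + 80 + 8, 8, i)) for i in range(ns)]
    pmax = [float(sig_fld(16 + 80 + 8 + 8, 8, i)) for i in range(ns)]
    dmin = [int(sig_fld(16 + 80 + 8 + 16, 8, i)) for i in range(ns)]
    dmax = [int(sig_fld(16 + 80 + 8 + 24, 8, i)) for i in range(ns)]
    spr = [int(sig_fld(16 + 80 + 8 + 32 + 80, 8, i)) for i in range(ns)]

    expected_size = hdr + n_records * sum(spr) * 2
    if len(raw) < expected_size:
        raise IntegrityError(
            f"{path}: file shorter than header promises "
            f"({len(raw)} < {expected_size} bytes)"
        )
    if strict and len(raw) != expected_size:
        raise IntegrityError(f"{path}: trailing bytes after last data record")

    rates = [s / record_dur for s in spr]
    if len(set(rates)) != 1:
        raise ValueError(f"{path}: heterogeneous per-channel sampling rates")
    fs = rates[0]
    if strict and abs(fs - expected_rate_hz) > 1e-6:
        raise ValueError(
            f"{path}: sampling rate {fs} Hz != expected {expected_rate_hz} Hz"
        )

    data = np.frombuffer(raw, dtype="<i2", offset=hdr, count=n_records * sum(spr))
    sig = np.empty((ns, n_records * spr[0]), dtype=np.float64)
    per_rec = sum(spr)
    for i in range(ns):
        off = sum(spr[:i])
        chunks = data.reshape(n_records, per_rec)[:, off : off + spr[i]]
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        sig[i] = (chunks.ravel().astype(np.float64) - dmin[i]) * scale + pmin[i]
    sig *= unit_scale

    if len(set(labels)) != len(labels):
        if not drop_duplicate_labels:
            raise ValueError(f"{path}: duplicated channel labels {labels}")
        keep, seen = [], set()
        for i, lab in enumerate(labels):
            if lab in seen:
                logger.warning("%s: dropping duplicate channel %r", path, lab)
                continue
            seen.add(lab)
            keep.append(i)
        labels = [labels[i] for i in keep]
        sig = sig[keep]

    if line_noise_hz is None:
        line_noise_hz = 50 if "line=50" in reserved else 60
    subject = fld(8, 80) or path.stem
    session = fld(88, 80) or path.stem
    return Recording(
        subject_id=subject,
        session_id=session,
        channel_labels=labels,
        sampling_rate_hz=fs,
        signal=sig,
        line_noise_hz=line_noise_hz,
    )


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def merge_intervals(intervals: list[SeizureInterval]) -> list[SeizureInterval]:
    """Merge overlapping/touching intervals per session and sort by onset."""
    out: list[SeizureInterval] = []
    by_session: dict[str, list[SeizureInterval]] = {}
    for iv in intervals:
        by_session.setdefault(iv.session_id, []).append(iv)
    for session in by_session:
        ivs = sorted(by_session[session], key=lambda iv: (iv.onset_s, iv.offset_s))
        merged = [ivs[0]]
        for iv in ivs[1:]:
            last = merged[-1]
            if iv.onset_s <= last.offset_s:
                if iv.offset_s > last.offset_s:
                    merged[-1] = SeizureInterval(session, last.onset_s, iv.offset_s)
            else:
                merged.append(iv)
        out.extend(merged)
    return sorted(out, key=lambda iv: (iv.session_id, iv.onset_s))


def parse_annotations(
    path: str | Path, known_sessions: set[str] | None = None
) -> list[SeizureInterval]:
    """Parse a ``session,onset_s,offset_s`` CSV (header row) into intervals.

    Overlapping intervals within a session are merged; rows for sessions not
    in ``known_sessions`` (when given) are kept with a warning.
    """
    path = Path(path)
    intervals: list[SeizureInterval] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        required = {"session", "onset_s", "offset_s"}
        if not required.issubset(set(reader.fieldnames)):
            raise ValueError(
                f"{path}: annotation CSV must have columns {sorted(required)}"
            )
        for row in reader:
            session = row["session"].strip()
            iv = SeizureInterval(session, float(row["onset_s"]), float(row["offset_s"]))
            if known_sessions is not None and session not in known_sessions:
                logger.warning("%s: unknown session %r (row kept)", path, session)
            intervals.append(iv)
    return merge_intervals(intervals) if intervals else []


def write_annotations(intervals: list[SeizureInterval], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["session", "onset_s", "offset_s"])
        for iv in sorted(intervals, key=lambda iv: (iv.session_id, iv.onset_s)):
            writer.writerow([iv.session_id, f"{iv.onset_s:g}", f"{iv.offset_s:g}"])
    return path


def parse_chbmit_summary(path: str | Path) -> list[SeizureInterval]:
    """Adapter for CHB-MIT ``*-summary.txt`` seizure annotation dialect."""
    path = Path(path)
    intervals: list[SeizureInterval] = []
    session = None
    onset = None
    for line in path.read_text().splitlines():
        line = line.strip()
        low = line.lower()
        if low.startswith("file name:"):
            session = line.split(":", 1)[1].strip()
            session = session.removesuffix(".edf")
        elif "seizure" in low and "start time" in low:
            onset = float(line.split(":", 1)[1].strip().split()[0])
        elif "seizure" in low and "end time" in low:
            offset = float(line.split(":", 1)[1].strip().split()[0])
            if session is None or onset is None:
                raise ValueError(f"{path}: seizure end before file/start line")
            intervals.append(SeizureInterval(session, onset, offset))
            onset = None
    return merge_intervals(intervals) if intervals else []


# ---------------------------------------------------------------------------
# Channel policy and resampling
# ---------------------------------------------------------------------------


def intersect_channels(recordings: list[Recording]) -> list[str]:
    """Channels common to all recordings, in the first recording's order."""
    if not recordings:
        raise ValueError("need at least one recording")
    common = set(recordings[0].channel_labels)
    for rec in recordings[1:]:
        common &= set(rec.channel_labels)
    if not common:
        raise ValueError("channel intersection is empty")
    return [ch for ch in recordings[0].channel_labels if ch in common]


def select_channels(rec: Recording, channels: list[str]) -> Recording:
    idx = [rec.channel_labels.index(ch) for ch in channels]
    return rec.copy_with(channel_labels=list(channels), signal=rec.signal[idx].copy())


def resample_recording(rec: Recording, target_hz: float) -> Recording:
    """Polyphase resampling to ``target_hz`` (duration preserved)."""
    if not target_hz > 0:
        raise ValueError("target_hz must be positive")
    if abs(target_hz - rec.sampling_rate_hz) < 1e-9:
        return rec.copy_with()
    ratio = Fraction(target_hz / rec.sampling_rate_hz).limit_denominator(1000)
    sig = sps.resample_poly(rec.signal, ratio.numerator, ratio.denominator, axis=1)
    n_target = int(round(rec.n_samples * target_hz / rec.sampling_rate_hz))
    sig = sig[:, :n_target]
    return rec.copy_with(signal=sig, sampling_rate_hz=float(target_hz))
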