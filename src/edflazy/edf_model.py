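"""Domain types for EDF/EDF+ recordings and a bit-exact header codec.

An EDF file consists of a fixed 256-byte static header, ``num_signals``
further 256-byte blocks of per-signal metadata (stored field-by-field, not
signal-by-signal), and ``num_records`` data records of interleaved signed
16-bit little-endian samples.

The codec keeps the original padded byte content of every header field it
parsed, so an unmodified header re-encodes byte-identically even when the
producer used unusual padding (leading zeros, trailing spaces inside
numbers, ...).  Fields whose value has been changed are re-formatted
canonically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timezone
from fractions import Fraction
from typing import Sequence

import numpy as np

from .errors import (
    EmptyRangeError,
    FieldFormatError,
    FieldOverflowError,
    HeaderConsistencyError,
    NonAsciiFieldError,
    StreamingFileError,
    TruncatedHeaderError,
)

__all__ = [
    "RecordingHeader",
    "SignalHeader",
    "TimeRange",
    "ByteRange",
    "ChannelSeries",
    "parse_headers",
    "write_headers",
    "digital_to_physical",
    "physical_to_digital",
    "record_size_bytes",
    "annotation_signal_indices",
    "ANNOTATION_LABEL",
]

ANNOTATION_LABEL = "EDF Annotations"

# (name, width) of the static header fields, in file order.
_STATIC_FIELDS = (
    ("version", 8),
    ("patient_id", 80),
    ("recording_id", 80),
    ("start_date", 8),
    ("start_time", 8),
    ("header_bytes", 8),
    ("reserved", 44),
    ("num_records", 8),
    ("record_duration_s", 8),
    ("num_signals", 4),
)

# (name, width) of the per-signal fields, in file order; each field is
# stored contiguously for all signals before the next field begins.
_SIGNAL_FIELDS = (
    ("label", 16),
    ("transducer", 80),
    ("physical_dimension", 8),
    ("physical_min", 8),
    ("physical_max", 8),
    ("digital_min", 8),
    ("digital_max", 8),
    ("prefiltering", 80),
    ("samples_per_record", 8),
    ("reserved", 32),
)


@dataclass
class RecordingHeader:
    """Static file-level metadata (the first 256 bytes)."""

    version: str = "0"
    patient_id: str = "X"
    recording_id: str = "X"
    start_date: date = date(2000, 1, 1)
    start_time: time = time(0, 0, 0)
    header_bytes: int = 0
    num_records: int = 0
    record_duration_s: Fraction = Fraction(1)
    num_signals: int = 1
    reserved: str = ""
    raw: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def total_duration_s(self) -> Fraction:
        return self.num_records * self.record_duration_s

    @property
    def start_datetime(self) -> datetime:
        return datetime.combine(self.start_date, self.start_time)

    @property
    def start_epoch_ms(self) -> int:
        """Recording start as UNIX epoch milliseconds (EDF times read as UTC)."""
        dt = self.start_datetime.replace(tzinfo=timezone.utc)
        return round(dt.timestamp() * 1000)


@dataclass
class SignalHeader:
    """Per-channel metadata from the dynamic header."""

    label: str
    samples_per_record: int
    physical_min: float = -1.0
    physical_max: float = 1.0
    digital_min: int = -32768
    digital_max: int = 32767
    transducer: str = ""
    physical_dimension: str = ""
    prefiltering: str = ""
    reserved: str = ""
    raw: dict = field(default_factory=dict, repr=False, compare=False)

    def sampling_rate_hz(self, record_duration_s: Fraction) -> Fraction:
        """Exact rational sampling rate: samples_per_record / record duration."""
        return Fraction(self.samples_per_record) / Fraction(record_duration_s)

    @property
    def is_annotation(self) -> bool:
        return self.label.strip() == ANNOTATION_LABEL


@dataclass(frozen=True)
class TimeRange:
    """Half-open interval ``[start_s, end_s)`` in seconds from recording start."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise EmptyRangeError(
                f"time range [{self.start_s}, {self.end_s}) is empty"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def clip(self, total_duration_s) -> "TimeRange":
        """Clip to ``[0, total_duration_s)``; raises if nothing remains."""
        start = max(0.0, float(self.start_s))
        end = min(float(total_duration_s), float(self.end_s))
        if not end > start:
            raise EmptyRangeError(
                f"time range [{self.start_s}, {self.end_s}) lies outside the "
                f"recording of {float(total_duration_s)} s"
            )
        return TimeRange(start, end)


@dataclass(frozen=True)
class ByteRange:
    """A contiguous span of bytes within an EDF file."""

    offset: int
    length: int

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class ChannelSeries:
    """Flat per-channel arrays of (timestamp, min, max).

    A single flat array per component — never one container object per
    sample.  For uncompressed data ``min_values == max_values`` and
    ``frequency_per_s`` is None.
    """

    channel_index: int
    timestamps_ms: np.ndarray
    min_values: np.ndarray
    max_values: np.ndarray
    frequency_per_s: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=np.float64)
        self.min_values = np.asarray(self.min_values, dtype=np.float64)
        self.max_values = np.asarray(self.max_values, dtype=np.float64)
        n = len(self.timestamps_ms)
        if len(self.min_values) != n or len(self.max_values) != n:
            raise ValueError("timestamps, mins and maxs must have equal length")
        if n > 1 and not np.all(np.diff(self.timestamps_ms) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.min_values > self.max_values):
            raise ValueError("min_values must not exceed max_values")

    def __len__(self) -> int:
        return len(self.timestamps_ms)

    @property
    def is_compressed(self) -> bool:
        return self.frequency_per_s is not None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChannelSeries):
            return NotImplemented
        return (
            self.channel_index == other.channel_index
            and self.frequency_per_s == other.frequency_per_s
            and np.array_equal(self.timestamps_ms, other.timestamps_ms)
            and np.array_equal(self.min_values, other.min_values)
            and np.array_equal(self.max_values, other.max_values)
        )


def _decode_field(raw: bytes, name: str) -> str:
    try:
        text = raw.decode("ascii")
    except UnicodeDecodeError as exc:
        raise NonAsciiFieldError(f"field {name!r} contains non-ASCII bytes") from exc
    return text.rstrip(" ")


def _parse_int(text: str, name: str) -> int:
    try:
        return int(text.strip())
    except ValueError as exc:
        raise FieldFormatError(f"field {name!r} is not an integer: {text!r}") from exc


def _parse_float(text: str, name: str) -> float:
    try:
        return float(text.strip())
    except ValueError as exc:
        raise FieldFormatError(f"field {name!r} is not a number: {text!r}") from exc


def _parse_fraction(text: str, name: str) -> Fraction:
    try:
        return Fraction(text.strip())
    except (ValueError, ZeroDivisionError) as exc:
        raise FieldFormatError(f"field {name!r} is not a number: {text!r}") from exc


def _parse_date(text: str) -> date:
    # dd.mm.yy; EDF+ clipping convention: yy >= 85 -> 19yy, else 20yy.
    parts = text.strip().split(".")
    if len(parts) != 3:
        raise FieldFormatError(f"start date not in dd.mm.yy form: {text!r}")
    try:
        dd, mm, yy = (int(p) for p in parts)
        year = 1900 + yy if yy >= 85 else 2000 + yy
        return date(year, mm, dd)
    except ValueError as exc:
        raise FieldFormatError(f"invalid start date: {text!r}") from exc


def _parse_time(text: str) -> time:
    parts = text.strip().split(".")
    if len(parts) != 3:
        raise FieldFormatError(f"start time not in hh.mm.ss form: {text!r}")
    try:
        hh, mm, ss = (int(p) for p in parts)
        return time(hh, mm, ss)
    except ValueError as exc:
        raise FieldFormatError(f"invalid start time: {text!r}") from exc


def parse_headers(raw_bytes: bytes) -> tuple[RecordingHeader, list[SignalHeader]]:
    """Decode the static and dynamic headers from the start of an EDF file.

    Raises :class:`TruncatedHeaderError`, :class:`FieldFormatError`,
    :class:`HeaderConsistencyError` or :class:`StreamingFileError`.
    """
    if len(raw_bytes) < 256:
        raise TruncatedHeaderError(
            f"need at least 256 bytes for the static header, got {len(raw_bytes)}"
        )

    fields: dict[str, str] = {}
    raw_fields: dict[str, bytes] = {}
    pos = 0
    for name, width in _STATIC_FIELDS:
        chunk = raw_bytes[pos : pos + width]
        raw_fields[name] = chunk
        fields[name] = _decode_field(chunk, name)
        pos += width

    num_signals = _parse_int(fields["num_signals"], "num_signals")
    if num_signals < 1:
        raise HeaderConsistencyError(f"num_signals must be >= 1, got {num_signals}")

    expected_header = 256 * (num_signals + 1)
    if len(raw_bytes) < expected_header:
        raise TruncatedHeaderError(
            f"header needs {expected_header} bytes for {num_signals} signals, "
            f"got {len(raw_bytes)}"
        )

    header_bytes = _parse_int(fields["header_bytes"], "header_bytes")
    if header_bytes != expected_header:
        raise HeaderConsistencyError(
            f"header_bytes field says {header_bytes} but "
            f"256*(num_signals+1) = {expected_header}"
        )

    num_records = _parse_int(fields["num_records"], "num_records")
    if num_records == -1:
        raise StreamingFileError(
            "num_records == -1 (recording still in progress) is unsupported"
        )
    if num_records < 0:
        raise HeaderConsistencyError(f"num_records must be >= 0, got {num_records}")

    record_duration = _parse_fraction(fields["record_duration_s"], "record_duration_s")
    if record_duration <= 0:
        raise HeaderConsistencyError(
            f"record_duration_s must be > 0, got {record_duration}"
        )

    rec = RecordingHeader(
        version=fields["version"],
        patient_id=fields["patient_id"],
        recording_id=fields["recording_id"],
        start_date=_parse_date(fields["start_date"]),
        start_time=_parse_time(fields["start_time"]),
        header_bytes=header_bytes,
        num_records=num_records,
        record_duration_s=record_duration,
        num_signals=num_signals,
        reserved=fields["reserved"],
        raw=raw_fields,
    )

    # The dynamic header stores one field across all signals before the next.
    sig_fields: dict[str, list[str]] = {}
    sig_raw: dict[str, list[bytes]] = {}
    for name, width in _SIGNAL_FIELDS:
        values, raws = [], []
        for _ in range(num_signals):
            chunk = raw_bytes[pos : pos + width]
            raws.append(chunk)
            values.append(_decode_field(chunk, name))
            pos += width
        sig_fields[name] = values
        sig_raw[name] = raws

    sigs: list[SignalHeader] = []
    for i in range(num_signals):
        spr = _parse_int(sig_fields["samples_per_record"][i], "samples_per_record")
        if spr < 1:
            raise HeaderConsistencyError(
                f"signal {i}: samples_per_record must be >= 1, got {spr}"
            )
        dmin = _parse_int(sig_fields["digital_min"][i], "digital_min")
        dmax = _parse_int(sig_fields["digital_max"][i], "digital_max")
        if not dmin < dmax:
            raise HeaderConsistencyError(
                f"signal {i}: digital_min {dmin} must be < digital_max {dmax}"
            )
        if dmin < -32768 or dmax > 32767:
            raise HeaderConsistencyError(
                f"signal {i}: digital range [{dmin}, {dmax}] exceeds 16-bit signed"
            )
        pmin = _parse_float(sig_fields["physical_min"][i], "physical_min")
        pmax = _parse_float(sig_fields["physical_max"][i], "physical_max")
        if pmin == pmax:
            raise HeaderConsistencyError(
                f"signal {i}: physical_min equals physical_max ({pmin})"
            )
        sigs.append(
            SignalHeader(
                label=sig_fields["label"][i],
                transducer=sig_fields["transducer"][i],
                physical_dimension=sig_fields["physical_dimension"][i],
                physical_min=pmin,
                physical_max=pmax,
                digital_min=dmin,
                digital_max=dmax,
                prefiltering=sig_fields["prefiltering"][i],
                samples_per_record=spr,
                reserved=sig_fields["reserved"][i],
                raw={name: sig_raw[name][i] for name, _ in _SIGNAL_FIELDS},
            )
        )
    return rec, sigs


def _format_number(value, width: int, name: str) -> str:
    """Shortest decimal representation of ``value`` fitting ``width`` chars."""
    if isinstance(value, Fraction):
        if value.denominator == 1:
            value = int(value)
        else:
            value = float(value)
    if isinstance(value, (int, np.integer)):
        text = str(int(value))
        if len(text) > width:
            raise FieldOverflowError(f"{name}={value} does not fit {width} chars")
        return text
    if float(value) == int(value) and abs(value) < 10**width:
        text = str(int(value))
        if len(text) <= width:
            return text
    for precision in range(width, 0, -1):
        text = f"{float(value):.{precision}g}"
        if len(text) <= width and "inf" not in text and "nan" not in text:
            return text
    raise FieldOverflowError(f"{name}={value!r} does not fit {width} chars")


def _encode_field(value, raw: bytes | None, width: int, name: str) -> bytes:
    """Encode one header field, re-using original bytes when still valid."""
    if isinstance(value, date) and not isinstance(value, datetime):
        text = f"{value.day:02d}.{value.month:02d}.{value.year % 100:02d}"
    elif isinstance(value, time):
        text = f"{value.hour:02d}.{value.minute:02d}.{value.second:02d}"
    elif isinstance(value, str):
        text = value
    else:
        text = _format_number(value, width, name)

    if raw is not None and len(raw) == width:
        # Bit-exact re-encode: keep the original bytes if they still decode
        # to the current value.
        try:
            decoded = raw.decode("ascii").rstrip(" ")
        except UnicodeDecodeError:
            decoded = None
        if decoded is not None and _raw_matches(value, decoded):
            return raw

    try:
        encoded = text.encode("ascii")
    except UnicodeEncodeError as exc:
        raise NonAsciiFieldError(f"field {name!r} is not ASCII: {text!r}") from exc
    if len(encoded) > width:
        raise FieldOverflowError(
            f"field {name!r} needs {len(encoded)} bytes but only {width} fit"
        )
    return encoded.ljust(width, b" ")


def _raw_matches(value, decoded: str) -> bool:
    try:
        if isinstance(value, str):
            return decoded == value
        if isinstance(value, date) and not isinstance(value, datetime):
            return _parse_date(decoded) == value
        if isinstance(value, time):
            return _parse_time(decoded) == value
        if isinstance(value, Fraction):
            return _parse_fraction(decoded, "") == value
        if isinstance(value, (int, np.integer)):
            return int(decoded.strip()) == int(value)
        return float(decoded.strip()) == float(value)
    except (FieldFormatError, ValueError):
        return False


def write_headers(rec: RecordingHeader, sigs: Sequence[SignalHeader]) -> bytes:
    """Encode headers to exactly ``256 * (num_signals + 1)`` bytes.

    ``parse_headers(write_headers(rec, sigs))`` reproduces the inputs, and
    for headers obtained from :func:`parse_headers` and not modified since,
    the output is byte-identical to the original file.
    """
    if len(sigs) != rec.num_signals:
        raise HeaderConsistencyError(
            f"num_signals={rec.num_signals} but {len(sigs)} signal headers given"
        )
    expected = 256 * (rec.num_signals + 1)
    if rec.header_bytes not in (0, expected):
        raise HeaderConsistencyError(
            f"header_bytes={rec.header_bytes}, expected {expected}"
        )

    out = bytearray()
    values = {
        "version": rec.version,
        "patient_id": rec.patient_id,
        "recording_id": rec.recording_id,
        "start_date": rec.start_date,
        "start_time": rec.start_time,
        "header_bytes": expected,
        "reserved": rec.reserved,
        "num_records": rec.num_records,
        "record_duration_s": rec.record_duration_s,
        "num_signals": rec.num_signals,
    }
    for name, width in _STATIC_FIELDS:
        out += _encode_field(values[name], rec.raw.get(name), width, name)

    for name, width in _SIGNAL_FIELDS:
        for sig in sigs:
            out += _encode_field(getattr(sig, name), sig.raw.get(name), width, name)

    assert len(out) == expected
    return bytes(out)


def digital_to_physical(d, sig: SignalHeader):
    """Linear calibration of digital sample values into physical units.

    Accepts scalars or numpy arrays; exact at both calibration endpoints.
    """
    if not sig.digital_min < sig.digital_max:
        raise HeaderConsistencyError("degenerate digital range")
    scale = (sig.physical_max - sig.physical_min) / (sig.digital_max - sig.digital_min)
    return sig.physical_min + (np.asarray(d, dtype=np.float64) - sig.digital_min) * scale


def physical_to_digital(p, sig: SignalHeader):
    """Inverse calibration, rounded to the nearest integer and clipped."""
    if not sig.digital_min < sig.digital_max:
        raise HeaderConsistencyError("degenerate digital range")
    scale = (sig.digital_max - sig.digital_min) / (sig.physical_max - sig.physical_min)
    d = np.rint((np.asarray(p, dtype=np.float64) - sig.physical_min) * scale
                + sig.digital_min)
    return np.clip(d, sig.digital_min, sig.digital_max).astype(np.int64)


def record_size_bytes(sigs: Sequence[SignalHeader]) -> int:
    """Byte size of one data record: 2 bytes per sample over all signals."""
    return 2 * sum(s.samples_per_record for s in sigs)


def annotation_signal_indices(sigs: Sequence[SignalHeader]) -> list[int]:
    """Indices of EDF+ 'EDF Annotations' channels (excluded from signal ops)."""
    return [i for i, s in enumerate(sigs) if s.is_annotation]


def copy_header(rec: RecordingHeader, **changes) -> RecordingHeader:
    """Copy a recording header, dropping preserved raw bytes of changed fields."""
    new = replace(rec, **changes)
    new.raw = {k: v for k, v in rec.raw.items() if k not in changes}
    return new
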