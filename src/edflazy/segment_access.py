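"""Time-range -> byte-range translation, pluggable loading strategies and
the viewport prefetch cache.

A :class:`LoadingStrategy` is anything with ``read(offset, length) -> bytes``
and ``size() -> int``.  Reads must be pure with respect to file content and
satisfy the concatenation property ``read(o, a) + read(o + a, b) ==
read(o, a + b)``.  :class:`SegmentCache` itself fulfils the strategy
contract, so it can be handed to any reader transparently.
"""

from __future__ import annotations

import math
import urllib.error
import urllib.request
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .edf_model import (
    ByteRange,
    ChannelSeries,
    RecordingHeader,
    SignalHeader,
    TimeRange,
    digital_to_physical,
    record_size_bytes,
)
from .errors import RangeNotSupportedError, ShortReadError, StrategyError

__all__ = [
    "LoadingStrategy",
    "LocalFileStrategy",
    "HttpRangeStrategy",
    "local_file_strategy",
    "http_range_strategy",
    "open_strategy",
    "time_range_to_byte_range",
    "read_segment",
    "extract_record_aligned",
    "CacheConfig",
    "SegmentCache",
]


@runtime_checkable
class LoadingStrategy(Protocol):
    """Byte-range access to some backing source of EDF data."""

    def read(self, offset: int, length: int) -> bytes: ...

    def size(self) -> int: ...


class LocalFileStrategy:
    """Range reads from a file on local disk."""

    def __init__(self, path):
        self.path = Path(path)
        if not self.path.is_file():
            raise StrategyError(f"no such file: {self.path}")
        self._size = self.path.stat().st_size

    def read(self, offset: int, length: int) -> bytes:
        with open(self.path, "rb") as fh:
            fh.seek(offset)
            data = fh.read(length)
        if len(data) != length:
            raise ShortReadError(
                f"wanted {length} bytes at offset {offset}, got {len(data)}"
            )
        return data

    def size(self) -> int:
        return self._size


class HttpRangeStrategy:
    """Range reads over HTTP.

    Sends a single ``Range: bytes=o-(o+l-1)`` request per read and insists
    on a 206 partial-content answer of exactly the requested length.  A
    server that ignores the header and replies 200 with the full body is
    reported via :class:`RangeNotSupportedError`, never silently buffered.
    """

    def __init__(self, url: str, timeout: float = 30.0):
        self.url = url
        self.timeout = timeout
        self._size: int | None = None

    def read(self, offset: int, length: int) -> bytes:
        if length <= 0:
            return b""
        req = urllib.request.Request(
            self.url, headers={"Range": f"bytes={offset}-{offset + length - 1}"}
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                if resp.status != 206:
                    raise RangeNotSupportedError(
                        f"server answered {resp.status} instead of 206 partial "
                        f"content; range requests unsupported at {self.url}"
                    )
                data = resp.read()
        except urllib.error.HTTPError as exc:
            raise StrategyError(f"HTTP error {exc.code} from {self.url}") from exc
        except urllib.error.URLError as exc:
            raise StrategyError(f"cannot reach {self.url}: {exc.reason}") from exc
        if len(data) != length:
            raise ShortReadError(
                f"wanted {length} bytes at offset {offset}, got {len(data)}"
            )
        return data

    def size(self) -> int:
        if self._size is None:
            req = urllib.request.Request(self.url, headers={"Range": "bytes=0-0"})
            try:
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    if resp.status == 206:
                        content_range = resp.headers.get("Content-Range", "")
                        # "bytes 0-0/12345"
                        self._size = int(content_range.rpartition("/")[2])
                    elif resp.status == 200:
                        raise RangeNotSupportedError(
                            f"server at {self.url} ignores Range headers"
                        )
                    else:
                        raise StrategyError(
                            f"unexpected status {resp.status} from {self.url}"
                        )
            except urllib.error.URLError as exc:
                raise StrategyError(f"cannot reach {self.url}: {exc}") from exc
        return self._size


def local_file_strategy(path) -> LocalFileStrategy:
    return LocalFileStrategy(path)


def http_range_strategy(url: str) -> HttpRangeStrategy:
    return HttpRangeStrategy(url)


def open_strategy(source: str) -> LoadingStrategy:
    """Pick a strategy from a path or an http(s) URL."""
    text = str(source)
    if text.startswith("http://") or text.startswith("https://"):
        return HttpRangeStrategy(text)
    return LocalFileStrategy(text)


def time_range_to_byte_range(
    t: TimeRange, rec: RecordingHeader, sigs: Sequence[SignalHeader]
) -> ByteRange:
    """Smallest record-aligned byte range covering the (clipped) time range.

    ``first_record = floor(start / record_duration)``,
    ``last_record = ceil(end / record_duration) - 1``.
    """
    t = t.clip(rec.total_duration_s)
    rd = Fraction(rec.record_duration_s)
    first_record = math.floor(Fraction(t.start_s) / rd)
    last_record = math.ceil(Fraction(t.end_s) / rd) - 1
    last_record = min(last_record, rec.num_records - 1)
    rsz = record_size_bytes(sigs)
    return ByteRange(
        offset=rec.header_bytes + first_record * rsz,
        length=(last_record - first_record + 1) * rsz,
    )


def _record_layout(sigs: Sequence[SignalHeader]) -> list[tuple[int, int]]:
    """Per signal: (sample offset within a record, samples_per_record)."""
    layout = []
    pos = 0
    for sig in sigs:
        layout.append((pos, sig.samples_per_record))
        pos += sig.samples_per_record
    return layout


def read_segment(
    strategy: LoadingStrategy,
    t: TimeRange,
    rec: RecordingHeader,
    sigs: Sequence[SignalHeader],
    calibrate: bool = True,
) -> list[ChannelSeries]:
    """Read and de-interleave the samples covering ``t``, one series per channel.

    The covering records are fetched in a single strategy read, the
    record-packed int16 samples are split into flat per-channel arrays,
    calibrated to physical units and trimmed to exactly ``[start_s, end_s)``.
    EDF+ annotation channels are skipped.
    """
    t = t.clip(rec.total_duration_s)
    br = time_range_to_byte_range(t, rec, sigs)
    raw = strategy.read(br.offset, br.length)
    if len(raw) != br.length:
        raise ShortReadError(f"expected {br.length} bytes, got {len(raw)}")

    rsz = record_size_bytes(sigs)
    n_records = br.length // rsz
    first_record = (br.offset - rec.header_bytes) // rsz
    samples = np.frombuffer(raw, dtype="<i2").reshape(n_records, rsz // 2)

    rd = Fraction(rec.record_duration_s)
    start_frac = Fraction(t.start_s)
    end_frac = Fraction(t.end_s)
    start_ms = rec.start_epoch_ms

    out: list[ChannelSeries] = []
    for idx, (col, spr) in enumerate(_record_layout(sigs)):
        sig = sigs[idx]
        if sig.is_annotation:
            continue
        fs = Fraction(spr) / rd  # exact rational sampling rate
        # Global sample indices available in the fetched records.
        g0 = first_record * spr
        values = samples[:, col : col + spr].reshape(-1)
        # Keep samples whose time g/fs falls in [start, end).
        lo = max(g0, math.ceil(start_frac * fs))
        hi = min(g0 + len(values), math.ceil(end_frac * fs))
        if hi <= lo:
            trimmed = values[:0]
            g_idx = np.arange(0)
        else:
            trimmed = values[lo - g0 : hi - g0]
            g_idx = np.arange(lo, hi)
        ts = start_ms + g_idx * (1000.0 / float(fs))
        phys = (
            digital_to_physical(trimmed, sig)
            if calibrate
            else trimmed.astype(np.float64)
        )
        out.append(
            ChannelSeries(
                channel_index=idx,
                timestamps_ms=ts,
                min_values=phys,
                max_values=phys.copy(),
                frequency_per_s=None,
                label=sig.label,
            )
        )
    return out


def extract_record_aligned(
    strategy: LoadingStrategy,
    t: TimeRange,
    rec: RecordingHeader,
    sigs: Sequence[SignalHeader],
) -> bytes:
    """A standalone EDF excerpt: the records covering ``t`` with a header
    whose start time and record count are shifted accordingly."""
    from datetime import timedelta

    from .edf_model import copy_header, write_headers

    t = t.clip(rec.total_duration_s)
    br = time_range_to_byte_range(t, rec, sigs)
    rsz = record_size_bytes(sigs)
    first_record = (br.offset - rec.header_bytes) // rsz
    n_records = br.length // rsz
    offset_s = float(first_record * Fraction(rec.record_duration_s))
    new_start = rec.start_datetime + timedelta(seconds=offset_s)
    new_rec = copy_header(
        rec,
        num_records=n_records,
        start_date=new_start.date(),
        start_time=new_start.time(),
    )
    return write_headers(new_rec, sigs) + strategy.read(br.offset, br.length)


@dataclass
class CacheConfig:
    """Prefetch policy: the viewport width W and how many widths to keep
    on each side (the default keeps two viewport widths left and right)."""

    viewport_width_s: float = 30.0
    prefetch_multiplier: int = 2

    def __post_init__(self) -> None:
        if not self.viewport_width_s > 0:
            raise ValueError("viewport_width_s must be > 0")
        if self.prefetch_multiplier < 0:
            raise ValueError("prefetch_multiplier must be >= 0")


class SegmentCache:
    """Record-aligned prefetch cache over a loading strategy.

    After :meth:`ensure_window` settles for a viewport ``t`` of width ``W``,
    the cache covers ``[t.start - 2W, t.end + 2W]`` clipped to the recording,
    and everything cached outside that span (beyond one record of alignment
    slack) has been evicted.  The cache itself satisfies the strategy
    contract; reads inside the covered span touch only cached bytes.
    """

    def __init__(
        self,
        strategy: LoadingStrategy,
        rec: RecordingHeader,
        sigs: Sequence[SignalHeader],
        config: CacheConfig | None = None,
    ):
        self.strategy = strategy
        self.rec = rec
        self.sigs = sigs
        self.config = config or CacheConfig()
        self._rsz = record_size_bytes(sigs)
        # Disjoint, sorted, merged blocks: (first_record, last_record_excl, bytes)
        self._blocks: list[tuple[int, int, bytes]] = []

    # -- cache maintenance -------------------------------------------------

    def _span_records(self, t: TimeRange) -> tuple[int, int]:
        """Record-aligned prefetch span for viewport ``t``, clipped."""
        w = t.duration_s * self.config.prefetch_multiplier
        total = float(self.rec.total_duration_s)
        start = max(0.0, t.start_s - w)
        end = min(total, t.end_s + w)
        rd = Fraction(self.rec.record_duration_s)
        rlo = math.floor(Fraction(start) / rd)
        rhi = min(math.ceil(Fraction(end) / rd), self.rec.num_records)
        return rlo, rhi

    def ensure_window(self, t: TimeRange) -> None:
        """Prefetch the ±2W span around viewport ``t`` and evict the rest.

        Fetches are coalesced (one strategy read per contiguous gap).  On a
        strategy failure, the cache state is left unchanged.
        """
        t = t.clip(self.rec.total_duration_s)
        rlo, rhi = self._span_records(t)

        kept: list[tuple[int, int, bytes]] = []
        for lo, hi, data in self._blocks:
            nlo, nhi = max(lo, rlo), min(hi, rhi)
            if nhi > nlo:
                off = (nlo - lo) * self._rsz
                kept.append((nlo, nhi, data[off : off + (nhi - nlo) * self._rsz]))

        # Contiguous uncovered gaps inside [rlo, rhi), one read each.
        gaps: list[tuple[int, int]] = []
        cursor = rlo
        for lo, hi, _ in kept:
            if lo > cursor:
                gaps.append((cursor, lo))
            cursor = max(cursor, hi)
        if cursor < rhi:
            gaps.append((cursor, rhi))

        fetched: list[tuple[int, int, bytes]] = []
        for lo, hi in gaps:  # read everything before mutating state
            offset = self.rec.header_bytes + lo * self._rsz
            fetched.append((lo, hi, self.strategy.read(offset, (hi - lo) * self._rsz)))

        blocks = sorted(kept + fetched)
        merged: list[tuple[int, int, bytes]] = []
        for lo, hi, data in blocks:
            if merged and merged[-1][1] == lo:
                plo, phi, pdata = merged[-1]
                merged[-1] = (plo, hi, pdata + data)
            else:
                merged.append((lo, hi, data))
        self._blocks = merged

    def covered_span_s(self) -> tuple[float, float] | None:
        """Time span of the (single, merged) cached block, or None if empty
        or fragmented."""
        if len(self._blocks) != 1:
            return None
        lo, hi, _ = self._blocks[0]
        rd = float(self.rec.record_duration_s)
        return lo * rd, hi * rd

    def get_cached(self, t: TimeRange) -> bytes | None:
        """Raw record bytes covering ``t`` if fully cached, else None."""
        t = t.clip(self.rec.total_duration_s)
        rd = Fraction(self.rec.record_duration_s)
        rlo = math.floor(Fraction(t.start_s) / rd)
        rhi = min(math.ceil(Fraction(t.end_s) / rd), self.rec.num_records)
        for lo, hi, data in self._blocks:
            if lo <= rlo and rhi <= hi:
                off = (rlo - lo) * self._rsz
                return data[off : off + (rhi - rlo) * self._rsz]
        return None

    # -- LoadingStrategy contract -----------------------------------------

    def read(self, offset: int, length: int) -> bytes:
        """Serve a byte range, using cached records where possible and the
        underlying strategy for everything else."""
        if length <= 0:
            return b""
        parts: list[bytes] = []
        pos = offset
        end = offset + length
        while pos < end:
            block = self._block_for(pos)
            if block is None:
                gap_end = min(end, self._next_cached_offset(pos))
                parts.append(self.strategy.read(pos, gap_end - pos))
                pos = gap_end
            else:
                lo, hi, data = block
                blk_off = self.rec.header_bytes + lo * self._rsz
                take_end = min(end, blk_off + len(data))
                parts.append(data[pos - blk_off : take_end - blk_off])
                pos = take_end
        return b"".join(parts)

    def size(self) -> int:
        return self.strategy.size()

    def _block_for(self, pos: int):
        for lo, hi, data in self._blocks:
            blk_off = self.rec.header_bytes + lo * self._rsz
            if blk_off <= pos < blk_off + len(data):
                return lo, hi, data
        return None

    def _next_cached_offset(self, pos: int) -> int:
        candidates = [
            self.rec.header_bytes + lo * self._rsz
            for lo, _, _ in self._blocks
            if self.rec.header_bytes + lo * self._rsz > pos
        ]
        return min(candidates) if candidates else (1 << 62)
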