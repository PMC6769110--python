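"""Display-resolution min-max compression of channel series.

Rendering more samples per pixel column than the column can show is wasted
work: the drawn extent of a column is fully determined by the column's
minimum and maximum.  Bucketing a channel at ``f`` buckets per second and
keeping only each bucket's extremes therefore preserves the drawn image
while discarding most samples.

``f`` counts buckets (min-max pairs), so the stored value rate is ``2*f``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .edf_model import ChannelSeries, RecordingHeader, SignalHeader, TimeRange
from .errors import EdfError
from .segment_access import LoadingStrategy, read_segment

__all__ = [
    "CompressionSpec",
    "bucket_keys",
    "compress_series",
    "get_data",
    "compression_gain",
    "pixels_per_second",
    "samples_per_column",
    "frame_period_ms",
]


def bucket_keys(
    timestamps_ms: np.ndarray, anchor_ms: float, bucket_ms: float
) -> np.ndarray:
    """Bucket index ``floor((ts - anchor) / bucket)`` per timestamp.

    Computed with a few-ulp tolerance: timestamps that sit exactly on a
    bucket boundary in real arithmetic can land one float ulp below it
    (absolute epoch milliseconds only resolve ~2e-4 ms around 1e12), which
    plain flooring would assign to the previous bucket.  The tolerance is
    far below any real inter-sample spacing, so off-boundary samples are
    unaffected.
    """
    scale = max(float(np.max(np.abs(timestamps_ms), initial=1.0)), abs(anchor_ms), 1.0)
    tol = max(4.0 * float(np.spacing(scale)) / bucket_ms, 1e-9)
    return np.floor((timestamps_ms - anchor_ms) / bucket_ms + tol).astype(np.int64)


@dataclass(frozen=True)
class CompressionSpec:
    """Bucket rate ``frequency_per_s`` against a source rate ``sampling_rate_hz``.

    Compression is only active when the source rate exceeds the bucket rate.
    """

    frequency_per_s: float
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        if not self.frequency_per_s > 0:
            raise EdfError(f"frequency must be > 0, got {self.frequency_per_s}")

    @property
    def active(self) -> bool:
        return self.sampling_rate_hz > self.frequency_per_s


def compress_series(
    series: ChannelSeries, frequency_per_s: float, anchor_ms: float | None = None
) -> ChannelSeries:
    """Reduce a series to per-bucket (start timestamp, min, max) triples.

    Bucket ``k`` spans ``[anchor + k/f, anchor + (k+1)/f)``; the anchor
    defaults to the first timestamp.  Empty buckets are omitted; a partial
    trailing bucket keeps the extremes of whatever samples it has.
    Compressing an already-compressed series takes min-of-mins and
    max-of-maxs, which makes the operation idempotent at a fixed ``f``.
    """
    if not frequency_per_s > 0:
        raise EdfError(f"frequency must be > 0, got {frequency_per_s}")
    if series.frequency_per_s == frequency_per_s and anchor_ms is None:
        # Already bucketed on this grid; re-bucketing is the identity.
        return series
    if len(series) == 0:
        return ChannelSeries(
            channel_index=series.channel_index,
            timestamps_ms=np.empty(0),
            min_values=np.empty(0),
            max_values=np.empty(0),
            frequency_per_s=float(frequency_per_s),
            label=series.label,
        )

    bucket_ms = 1000.0 / frequency_per_s
    if anchor_ms is None:
        anchor_ms = float(series.timestamps_ms[0])
    keys = bucket_keys(series.timestamps_ms, anchor_ms, bucket_ms)

    uniq, starts = np.unique(keys, return_index=True)
    mins = np.minimum.reduceat(series.min_values, starts)
    maxs = np.maximum.reduceat(series.max_values, starts)
    ts = anchor_ms + uniq * bucket_ms
    return ChannelSeries(
        channel_index=series.channel_index,
        timestamps_ms=ts,
        min_values=mins,
        max_values=maxs,
        frequency_per_s=float(frequency_per_s),
        label=series.label,
    )


def get_data(
    strategy: LoadingStrategy,
    t: TimeRange,
    rec: RecordingHeader,
    sigs: Sequence[SignalHeader],
    frequency: float | None = None,
) -> list[ChannelSeries]:
    """Read a time range, optionally compressed to at most ``frequency``
    min-max buckets per second per channel.

    Channels whose sampling rate does not exceed ``frequency`` pass through
    uncompressed; without ``frequency`` every channel is uncompressed
    (``min == max``).
    """
    if frequency is not None and not frequency > 0:
        raise EdfError(f"frequency must be > 0, got {frequency}")
    t = t.clip(rec.total_duration_s)
    raw = read_segment(strategy, t, rec, sigs)
    if frequency is None:
        return raw
    anchor_ms = rec.start_epoch_ms + t.start_s * 1000.0
    out = []
    for series in raw:
        fs = float(sigs[series.channel_index].sampling_rate_hz(rec.record_duration_s))
        if fs <= frequency:
            out.append(series)
        else:
            out.append(compress_series(series, frequency, anchor_ms=anchor_ms))
    return out


def compression_gain(sampling_rate_hz: float, frequency_per_s: float) -> float:
    """Percentage of samples eliminated by min-max compression.

    Each bucket stores two values, so the retained fraction is
    ``2 f / fs`` and the gain is ``max(0, 1 - min(1, 2 f / fs)) * 100``.
    """
    if not sampling_rate_hz > 0 or not frequency_per_s > 0:
        raise EdfError("rates must be > 0")
    retained = min(1.0, 2.0 * frequency_per_s / sampling_rate_hz)
    return max(0.0, 1.0 - retained) * 100.0


def pixels_per_second(width_px: int, window_s: float) -> float:
    """Horizontal pixels available per second of signal in a window."""
    if width_px < 1 or not window_s > 0:
        raise EdfError("width_px must be >= 1 and window_s > 0")
    return width_px / window_s


def samples_per_column(sampling_rate_hz: float, px_per_second: float) -> int:
    """Whole number of samples sharing one pixel column."""
    if not sampling_rate_hz > 0 or not px_per_second > 0:
        raise EdfError("rates must be > 0")
    return math.floor(sampling_rate_hz / px_per_second)


def frame_period_ms(refresh_hz: float = 60.0) -> int:
    """Display frame period in whole milliseconds — the floor on perceivable
    update latency."""
    if not refresh_hz > 0:
        raise EdfError("refresh_hz must be > 0")
    return math.floor(1000.0 / refresh_hz)
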