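"""Event/annotation model with a JSON interchange format.

Two dialects are supported.  The *literal* dialect is a single JSON object
whose keys are decimal UNIX-epoch-millisecond strings and whose values are
plain label strings — point events only, so range ends and channel
references are dropped on export.  The *extended* dialect keeps the same
keys but uses structured values ``{"label": ..., "end_ms": ..., "channel":
...}`` and is lossless.  Import auto-detects the dialect per value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

from .errors import EventError

__all__ = [
    "Event",
    "EventSet",
    "export_events",
    "import_events",
    "ingest_external_events",
    "validate_hypnogram",
    "SLEEP_STAGES",
    "EPOCH_MS",
    "DEFAULT_APNEA_LABELS",
]

SLEEP_STAGES = ("W", "N1", "N2", "N3", "R")
EPOCH_MS = 30_000  # one scoring epoch

# Shortcut vocabulary for common apnea labels; configurable, not canonical.
DEFAULT_APNEA_LABELS = (
    "Obstructive Apnea",
    "Central Apnea",
    "Mixed Apnea",
    "Hypopnea",
)


@dataclass(frozen=True)
class Event:
    """A labeled time point or range, in absolute epoch milliseconds."""

    start_ms: int
    label: str
    end_ms: int | None = None
    channel: str | None = None
    source: str | None = None  # provenance tag; not part of identity

    def __post_init__(self) -> None:
        if self.end_ms is not None and not self.end_ms > self.start_ms:
            raise EventError(
                f"end_ms {self.end_ms} must be > start_ms {self.start_ms}"
            )

    @property
    def duration_ms(self) -> int | None:
        return None if self.end_ms is None else self.end_ms - self.start_ms

    @property
    def key(self) -> tuple:
        """Deduplication identity: (start, end, label, channel)."""
        return (self.start_ms, self.end_ms, self.label, self.channel)

    def _sort_key(self) -> tuple:
        return (self.start_ms, self.label)


class EventSet:
    """An ordered collection of events, sorted by start time (ties by label)."""

    def __init__(self, events: Iterable[Event] = ()):
        self._events = sorted(events, key=Event._sort_key)

    def __len__(self) -> int:
        return len(self._events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self._events)

    def __getitem__(self, i: int) -> Event:
        return self._events[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventSet):
            return NotImplemented
        return [e.key for e in self] == [e.key for e in other]

    def __repr__(self) -> str:
        return f"EventSet({self._events!r})"

    def add(self, event: Event) -> "EventSet":
        return EventSet([*self._events, event])

    def remove(self, event: Event) -> "EventSet":
        """Remove the event with this identity; unknown events fail."""
        matches = [e for e in self._events if e.key == event.key]
        if not matches:
            raise EventError(f"no such event: {event.key}")
        remaining = list(self._events)
        remaining.remove(matches[0])
        return EventSet(remaining)

    def move(self, event: Event, delta_ms: int) -> "EventSet":
        """Shift an event in time; its duration is preserved."""
        target = self._find(event)
        moved = replace(
            target,
            start_ms=target.start_ms + delta_ms,
            end_ms=None if target.end_ms is None else target.end_ms + delta_ms,
        )
        return self.remove(target).add(moved)

    def resize(
        self,
        event: Event,
        new_start_ms: int | None = None,
        new_end_ms: int | None = None,
    ) -> "EventSet":
        """Change one or both bounds of a range event; inverted ranges fail."""
        target = self._find(event)
        if target.end_ms is None:
            raise EventError("cannot resize a point event")
        start = target.start_ms if new_start_ms is None else new_start_ms
        end = target.end_ms if new_end_ms is None else new_end_ms
        if not end > start:
            raise EventError(f"resize would invert the range: [{start}, {end}]")
        return self.remove(target).add(replace(target, start_ms=start, end_ms=end))

    def merge(self, other: "EventSet") -> "EventSet":
        """Union, deduplicated on (start, end, label, channel); the first
        occurrence (and its source tag) wins for duplicates."""
        seen: dict[tuple, Event] = {}
        for event in [*self._events, *other]:
            seen.setdefault(event.key, event)
        return EventSet(seen.values())

    def _find(self, event: Event) -> Event:
        for e in self._events:
            if e.key == event.key:
                return e
        raise EventError(f"no such event: {event.key}")


def export_events(es: EventSet, dialect: str = "literal") -> str:
    """Serialize to JSON; keys are emitted in ascending numeric order.

    The literal dialect maps start-millisecond strings to label strings and
    cannot hold two events at one timestamp: colliding events are nudged by
    +1 ms with a warning.  The extended dialect is lossless.
    """
    if dialect not in ("literal", "extended"):
        raise EventError(f"unknown dialect {dialect!r}")
    obj: dict[str, object] = {}
    for event in es:
        ts = event.start_ms
        while str(ts) in obj:
            ts += 1
        if ts != event.start_ms:
            warnings.warn(
                f"event {event.label!r} at {event.start_ms} collides; "
                f"nudged to {ts}",
                stacklevel=2,
            )
        if dialect == "literal":
            obj[str(ts)] = event.label
        else:
            value: dict[str, object] = {"label": event.label}
            if event.end_ms is not None:
                value["end_ms"] = event.end_ms
            if event.channel is not None:
                value["channel"] = event.channel
            obj[str(ts)] = value
    return json.dumps(obj, indent=1)


def import_events(text: str, source: str | None = None) -> EventSet:
    """Parse either dialect (auto-detected per value)."""
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise EventError(f"malformed JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise EventError("event JSON must be a single object")
    events = []
    for key, value in obj.items():
        try:
            start_ms = int(key)
        except ValueError as exc:
            raise EventError(f"non-numeric timestamp key {key!r}") from exc
        if isinstance(value, str):
            events.append(Event(start_ms=start_ms, label=value, source=source))
        elif isinstance(value, dict) and "label" in value:
            events.append(
                Event(
                    start_ms=start_ms,
                    label=str(value["label"]),
                    end_ms=value.get("end_ms"),
                    channel=value.get("channel"),
                    source=source,
                )
            )
        else:
            raise EventError(f"unsupported event value for key {key!r}: {value!r}")
    return EventSet(events)


def ingest_external_events(
    text: str, es: EventSet, source: str = "external"
) -> EventSet:
    """Merge externally produced events (e.g. detected artifacts) into an
    existing set, deduplicating on identity and keeping the source tag."""
    return es.merge(import_events(text, source=source))


def validate_hypnogram(
    es: EventSet, recording_start_ms: int, recording_end_ms: int
) -> list[str]:
    """Check that sleep-stage events tile the recording in 30 s epochs.

    Stages are ordinary range events with reserved labels.  Returns a list
    of problems (empty means a valid hypnogram): wrong duration, overlap,
    gaps, or no stage events at all.
    """
    stages = [e for e in es if e.label in SLEEP_STAGES]
    problems: list[str] = []
    if not stages:
        return ["no sleep-stage events found"]
    cursor = recording_start_ms
    for event in stages:
        if event.end_ms is None:
            problems.append(f"stage {event.label} at {event.start_ms} has no end")
            continue
        if event.duration_ms != EPOCH_MS:
            problems.append(
                f"stage {event.label} at {event.start_ms} lasts "
                f"{event.duration_ms} ms, expected {EPOCH_MS}"
            )
        if event.start_ms > cursor:
            problems.append(f"gap from {cursor} to {event.start_ms}")
        elif event.start_ms < cursor:
            problems.append(f"overlap at {event.start_ms}")
        cursor = max(cursor, event.end_ms)
    if cursor < recording_end_ms:
        problems.append(f"uncovered tail from {cursor} to {recording_end_ms}")
    return problems
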