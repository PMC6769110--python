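"""Header pseudonymization with a persistent, exportable mapping.

The local patient identification field is the only EDF header field meant
to carry identity.  Before a recording leaves the machine, that field is
replaced by a randomly generated pseudonym; the original <-> pseudonym
mapping lives in a persistent key-value store that can be exported to and
re-imported from XLSX or CSV.
"""

from __future__ import annotations

import csv
import json
import random
from datetime import datetime, timezone
from pathlib import Path

from openpyxl import Workbook, load_workbook

from .edf_model import (
    RecordingHeader,
    copy_header,
    parse_headers,
    write_headers,
)
from .errors import MappingConflictError, PseudonymCollisionError, TableFormatError

__all__ = [
    "PseudonymStore",
    "pseudonymize",
    "pseudonymize_file",
    "export_mapping",
    "import_mapping",
    "PSEUDONYM_ALPHABET",
    "PSEUDONYM_LENGTH",
]

# Unambiguous uppercase+digit alphabet (no 0/O, 1/I): human-transcribable,
# and 12 characters fit the 80-byte patient field with room to spare.
PSEUDONYM_ALPHABET = "ABCDEFGHJKLMNPQRSTUVWXYZ23456789"
PSEUDONYM_LENGTH = 12
_MAX_RETRIES = 1000

SCRUBBED_RECORDING_ID = "Startdate X X X X"


class PseudonymStore:
    """Persistent, injective original -> pseudonym mapping.

    Backed by a JSON file; every mutation is flushed, so the store survives
    process restarts.  A seed makes pseudonym generation reproducible.
    """

    def __init__(self, path=None, seed: int | None = None):
        self.path = Path(path) if path is not None else None
        self._rng = random.Random(seed)
        self._forward: dict[str, str] = {}
        self._created: dict[str, str] = {}
        if self.path is not None and self.path.exists():
            self._load()

    def _load(self) -> None:
        data = json.loads(self.path.read_text(encoding="utf-8"))
        self._forward = {str(k): str(v["pseudonym"]) for k, v in data.items()}
        self._created = {str(k): str(v.get("created_at", "")) for k, v in data.items()}
        self._check_injective()

    def _flush(self) -> None:
        if self.path is None:
            return
        data = {
            original: {
                "pseudonym": pseudonym,
                "created_at": self._created.get(original, ""),
            }
            for original, pseudonym in self._forward.items()
        }
        self.path.write_text(
            json.dumps(data, indent=1, sort_keys=True), encoding="utf-8"
        )

    def _check_injective(self) -> None:
        if len(set(self._forward.values())) != len(self._forward):
            raise MappingConflictError("store maps two originals to one pseudonym")

    def __len__(self) -> int:
        return len(self._forward)

    def __contains__(self, original: str) -> bool:
        return original in self._forward

    def items(self):
        return self._forward.items()

    def created_at(self, original: str) -> str:
        return self._created.get(original, "")

    def _generate(self) -> str:
        return "".join(
            self._rng.choice(PSEUDONYM_ALPHABET) for _ in range(PSEUDONYM_LENGTH)
        )

    def pseudonym_for(self, original: str) -> str:
        """Return the stored pseudonym, generating one on first sight."""
        if original in self._forward:
            return self._forward[original]
        taken = set(self._forward.values())
        for _ in range(_MAX_RETRIES):
            candidate = self._generate()
            if candidate not in taken:
                break
        else:
            raise PseudonymCollisionError(
                f"no fresh pseudonym found in {_MAX_RETRIES} attempts"
            )
        self._forward[original] = candidate
        self._created[original] = datetime.now(timezone.utc).isoformat(
            timespec="seconds"
        )
        self._flush()
        return candidate

    def add(self, original: str, pseudonym: str, created_at: str = "") -> None:
        """Insert an explicit pair; contradictions with existing pairs fail."""
        existing = self._forward.get(original)
        if existing is not None and existing != pseudonym:
            raise MappingConflictError(
                f"original {original!r} already maps to {existing!r}, "
                f"refusing {pseudonym!r}"
            )
        if existing is None and pseudonym in set(self._forward.values()):
            raise MappingConflictError(
                f"pseudonym {pseudonym!r} already taken by another original"
            )
        self._forward[original] = pseudonym
        if created_at or original not in self._created:
            self._created[original] = created_at
        self._flush()


def pseudonymize(
    rec: RecordingHeader,
    store: PseudonymStore,
    scrub_recording_id: bool = False,
) -> RecordingHeader:
    """Return a copy of the header with the patient field pseudonymized.

    The whole 80-character patient field (name, birth date and any EDF+
    subfields) is replaced as a unit.  The same original always yields the
    same pseudonym within one store.  With ``scrub_recording_id`` the free
    text of the recording identification field is also blanked.
    """
    changes: dict = {"patient_id": store.pseudonym_for(rec.patient_id)}
    if scrub_recording_id:
        changes["recording_id"] = SCRUBBED_RECORDING_ID
    return copy_header(rec, **changes)


def pseudonymize_file(
    in_path,
    out_path,
    store: PseudonymStore,
    enabled: bool = True,
    scrub_recording_id: bool = False,
) -> str | None:
    """Write a pseudonymized copy of an EDF file.

    Only header bytes inside the patient field (and optionally the
    recording field) change; all other header bytes and all signal data are
    copied verbatim.  With ``enabled=False`` the copy is byte-identical.
    Returns the pseudonym used, or None when disabled.
    """
    in_path, out_path = Path(in_path), Path(out_path)
    raw = in_path.read_bytes()
    if not enabled:
        out_path.write_bytes(raw)
        return None
    rec, sigs = parse_headers(raw)
    new_rec = pseudonymize(rec, store, scrub_recording_id=scrub_recording_id)
    header = write_headers(new_rec, sigs)
    out_path.write_bytes(header + raw[rec.header_bytes :])
    return new_rec.patient_id


_COLUMNS = ("original", "pseudonym", "created_at")


def export_mapping(store: PseudonymStore, path) -> None:
    """Export the mapping as XLSX or CSV (by file extension), columns
    ``original, pseudonym, created_at``."""
    path = Path(path)
    rows = [
        (original, pseudonym, store.created_at(original))
        for original, pseudonym in sorted(store.items())
    ]
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_COLUMNS)
            writer.writerows(rows)
    else:
        wb = Workbook()
        ws = wb.active
        ws.title = "pseudonyms"
        ws.append(list(_COLUMNS))
        for row in rows:
            ws.append(list(row))
        wb.save(path)


def import_mapping(path, store: PseudonymStore | None = None) -> PseudonymStore:
    """Import a mapping file, merging into ``store`` (or a fresh in-memory
    one).  Pairs contradicting the existing mapping raise
    :class:`MappingConflictError`; exact duplicates are fine."""
    path = Path(path)
    if store is None:
        store = PseudonymStore()
    if path.suffix.lower() == ".csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            rows = list(reader)
    else:
        wb = load_workbook(path, read_only=True)
        ws = wb.active
        rows = [
            ["" if c is None else str(c) for c in row]
            for row in ws.iter_rows(values_only=True)
        ]
        wb.close()
    if not rows or [c.strip() for c in rows[0][:2]] != ["original", "pseudonym"]:
        raise TableFormatError(f"{path}: expected header {_COLUMNS[:2]}")
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) < 2 or not row[0] or not row[1]:
            raise TableFormatError(f"{path}:{lineno}: malformed row {row!r}")
        created = row[2] if len(row) > 2 else ""
        store.add(str(row[0]), str(row[1]), created_at=str(created))
    return store
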