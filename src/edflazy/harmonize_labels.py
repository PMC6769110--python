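"""Harmonize vendor-specific channel labels to EDF+ standard names.

Label compliance across recording devices is low: the same signal appears
as ``C4-A1``, ``EEGC4-A1`` or ``EEG C4-A1``, or under an entirely local
name like ``LEGBEINLI``.  Matching runs on a normalized key (uppercase,
whitespace-collapsed, leading modality token stripped), looked up in a
manually compiled variant table.  Unknown labels pass through unchanged and
flagged — never guessed.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import TableFormatError

__all__ = [
    "HarmonizationTable",
    "TableEntry",
    "normalize_key",
    "harmonize",
    "load_table",
    "save_table",
    "seed_table",
    "UNKNOWN_CATEGORY",
]

UNKNOWN_CATEGORY = "unknown"

_MODALITY_TOKENS = ("EEG", "EMG", "EOG", "ECG")
_SEPARATORS = " -_:."


@dataclass(frozen=True)
class TableEntry:
    standard: str
    category: str
    provenance: str = ""  # source variant spelling, for reports


@dataclass
class HarmonizationTable:
    """Normalized-variant-key -> (standard label, modality category)."""

    entries: dict[str, TableEntry] = field(default_factory=dict)

    def add(self, variant: str, standard: str, category: str) -> None:
        key = normalize_key(variant)
        existing = self.entries.get(key)
        if existing is not None and existing.standard != standard:
            raise TableFormatError(
                f"variant {variant!r} (key {key!r}) maps to both "
                f"{existing.standard!r} and {standard!r}"
            )
        if existing is None:
            self.entries[key] = TableEntry(standard, category, provenance=variant)
        # Every standard label must be its own fixed point.
        std_key = normalize_key(standard)
        if std_key not in self.entries:
            self.entries[std_key] = TableEntry(standard, category, provenance=standard)

    def standards(self) -> list[str]:
        return sorted({e.standard for e in self.entries.values()})


def normalize_key(raw: str) -> str:
    """Canonical matching key for a channel label.

    Uppercases, trims, collapses internal whitespace, and strips one leading
    modality token (EEG/EMG/EOG/ECG) together with any separators that
    follow it.  A label that *is* a bare modality token stays itself.
    """
    key = re.sub(r"\s+", " ", raw.strip()).upper()
    for token in _MODALITY_TOKENS:
        if key.startswith(token):
            stripped = key[len(token):].lstrip(_SEPARATORS)
            if stripped:
                return stripped
            return key
    return key


def harmonize(raw: str, table: HarmonizationTable) -> tuple[str, bool, str]:
    """Map a raw label to ``(standard label, matched, category)``.

    Unmatched labels are returned unchanged with ``matched=False`` and
    category :data:`UNKNOWN_CATEGORY`.
    """
    entry = table.entries.get(normalize_key(raw))
    if entry is None:
        return raw, False, UNKNOWN_CATEGORY
    return entry.standard, True, entry.category


def load_table(path) -> HarmonizationTable:
    """Load a CSV table with header ``variant,standard,category``.

    Rows whose variant normalizes to the same key must agree on the
    standard; conflicts raise :class:`TableFormatError`.
    """
    table = HarmonizationTable()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"variant", "standard", "category"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise TableFormatError(
                f"{path}: header must contain columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            variant = (row.get("variant") or "").strip()
            standard = (row.get("standard") or "").strip()
            category = (row.get("category") or "").strip()
            if not variant or not standard or not category:
                raise TableFormatError(f"{path}:{lineno}: incomplete row {row!r}")
            table.add(variant, standard, category)
    return table


def save_table(table: HarmonizationTable, path) -> None:
    """Write a canonical (key-sorted) CSV serialization."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["variant", "standard", "category"])
        for key in sorted(table.entries):
            entry = table.entries[key]
            writer.writerow([entry.provenance or key, entry.standard, entry.category])


def seed_table() -> HarmonizationTable:
    """The small bundled table: in-repo variant examples plus standard
    self-entries; larger site tables load from CSV in the same format."""
    ref = resources.files("edflazy.data") / "harmonization_seed.csv"
    with resources.as_file(ref) as path:
        return load_table(Path(path))
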