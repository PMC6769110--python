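"""Deterministic synthetic EDF generation.

Every test in the suite runs against files produced here: structurally
valid EDF with fully known content (exact digital samples per channel), so
round trips, partial reads and compression all have a ground truth to
compare against.  The same seed always yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import date, datetime, time
from fractions import Fraction
from pathlib import Path

import numpy as np

from .edf_model import (
    RecordingHeader,
    SignalHeader,
    physical_to_digital,
    record_size_bytes,
    write_headers,
)
from .errors import EdfError

__all__ = ["ChannelSpec", "FixtureSpec", "GroundTruth", "generate_edf",
           "generate_psg_like"]

WAVEFORMS = ("sine", "square", "gaussian-noise", "ramp", "constant")


@dataclass(frozen=True)
class ChannelSpec:
    label: str
    fs: float  # sampling rate in Hz
    waveform: str = "sine"
    amplitude: float = 100.0
    physical_min: float = -200.0
    physical_max: float = 200.0
    digital_min: int = -32768
    digital_max: int = 32767
    physical_dimension: str = "uV"
    wave_hz: float = 1.0  # oscillation rate for sine/square

    def __post_init__(self) -> None:
        if self.waveform not in WAVEFORMS:
            raise EdfError(f"unknown waveform {self.waveform!r}")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    duration_s: float = 10.0
    record_duration_s: Fraction = Fraction(1)
    channels: tuple[ChannelSpec, ...] = (ChannelSpec("EEG C4-A1", 100.0),)
    patient_id: str = "PAT001 X 01-JAN-1980 Test_Patient"
    recording_id: str = "Startdate 01-JAN-2019 PSG Test"
    start: datetime = datetime(2019, 1, 1, 22, 0, 0)


@dataclass
class GroundTruth:
    """What generate_edf actually wrote: headers, raw bytes, exact samples."""

    spec: FixtureSpec
    rec: RecordingHeader
    sigs: list[SignalHeader]
    digital: list[np.ndarray]  # per channel, whole-recording int16 samples
    raw_bytes: bytes

    def physical(self, channel: int) -> np.ndarray:
        from .edf_model import digital_to_physical

        return digital_to_physical(self.digital[channel], self.sigs[channel])


def _channel_digital(
    ch: ChannelSpec, n_samples: int, rng: np.random.Generator, sig: SignalHeader
) -> np.ndarray:
    peak = max(abs(ch.physical_min), abs(ch.physical_max))
    if ch.waveform != "ramp" and abs(ch.amplitude) > peak:
        raise EdfError(
            f"{ch.label!r}: amplitude {ch.amplitude} exceeds the physical "
            f"range [{ch.physical_min}, {ch.physical_max}]"
        )
    t = np.arange(n_samples) / ch.fs
    if ch.waveform == "constant":
        phys = np.full(n_samples, float(ch.amplitude))
    elif ch.waveform == "sine":
        phys = ch.amplitude * np.sin(2 * np.pi * ch.wave_hz * t)
    elif ch.waveform == "square":
        phys = ch.amplitude * np.where(np.sin(2 * np.pi * ch.wave_hz * t) >= 0, 1, -1)
    elif ch.waveform == "gaussian-noise":
        phys = np.clip(
            rng.normal(0.0, ch.amplitude / 3.0, n_samples),
            -ch.amplitude,
            ch.amplitude,
        )
    elif ch.waveform == "ramp":
        # Strictly increasing digital staircase within each record span.
        spr = sig.samples_per_record
        span = ch.digital_max - ch.digital_min
        if spr > span + 1:
            raise EdfError(
                f"{ch.label!r}: {spr} samples per record exceed the digital "
                f"span of {span + 1} distinct values"
            )
        one_record = ch.digital_min + np.arange(spr, dtype=np.int64)
        reps = -(-n_samples // spr)
        return np.tile(one_record, reps)[:n_samples].astype(np.int16)
    else:  # pragma: no cover - guarded in ChannelSpec
        raise EdfError(ch.waveform)
    return physical_to_digital(phys, sig).astype(np.int16)


def generate_edf(spec: FixtureSpec, path=None) -> GroundTruth:
    """Build a valid EDF file from a spec; optionally write it (plus a JSON
    ground-truth sidecar) to ``path``.

    Raises if any channel's ``fs * record_duration`` is not integral or a
    waveform would leave its digital range.
    """
    rd = Fraction(spec.record_duration_s)
    num_records_frac = Fraction(spec.duration_s) / rd
    if num_records_frac.denominator != 1:
        raise EdfError(
            f"duration {spec.duration_s} s is not a whole number of "
            f"{float(rd)} s records"
        )
    num_records = int(num_records_frac)

    sigs: list[SignalHeader] = []
    for ch in spec.channels:
        spr_frac = Fraction(ch.fs) * rd
        if spr_frac.denominator != 1 or spr_frac < 1:
            raise EdfError(
                f"{ch.label!r}: fs {ch.fs} Hz gives a non-integral "
                f"{float(spr_frac)} samples per record"
            )
        sigs.append(
            SignalHeader(
                label=ch.label,
                samples_per_record=int(spr_frac),
                physical_min=ch.physical_min,
                physical_max=ch.physical_max,
                digital_min=ch.digital_min,
                digital_max=ch.digital_max,
                physical_dimension=ch.physical_dimension,
                transducer="synthetic",
            )
        )

    rec = RecordingHeader(
        version="0",
        patient_id=spec.patient_id,
        recording_id=spec.recording_id,
        start_date=spec.start.date(),
        start_time=time(spec.start.hour, spec.start.minute, spec.start.second),
        header_bytes=256 * (len(sigs) + 1),
        num_records=num_records,
        record_duration_s=rd,
        num_signals=len(sigs),
    )

    rng = np.random.default_rng(spec.seed)
    digital = [
        _channel_digital(ch, num_records * sig.samples_per_record, rng, sig)
        for ch, sig in zip(spec.channels, sigs)
    ]

    # Interleave into records: per record, each channel's block in turn.
    rsz = record_size_bytes(sigs)
    data = np.empty(num_records * rsz // 2, dtype="<i2")
    pos = 0
    for r in range(num_records):
        for sig, samples in zip(sigs, digital):
            spr = sig.samples_per_record
            data[pos : pos + spr] = samples[r * spr : (r + 1) * spr]
            pos += spr

    raw = write_headers(rec, sigs) + data.tobytes()
    truth = GroundTruth(spec=spec, rec=rec, sigs=sigs, digital=digital, raw_bytes=raw)

    if path is not None:
        path = Path(path)
        path.write_bytes(raw)
        sidecar = {
            "seed": spec.seed,
            "duration_s": spec.duration_s,
            "record_duration_s": str(rd),
            "num_records": num_records,
            "file_size": len(raw),
            "sha256": hashlib.sha256(raw).hexdigest(),
            "channels": [
                {
                    "label": ch.label,
                    "fs": ch.fs,
                    "waveform": ch.waveform,
                    "samples_per_record": sig.samples_per_record,
                }
                for ch, sig in zip(spec.channels, sigs)
            ],
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1), encoding="utf-8"
        )
    return truth


# Vendor-style variant labels from the bundled harmonization table, with
# plausible per-modality rates and waveforms.  Rates are kept low so a
# whole-night-shaped fixture stays well under a megabyte.
_PSG_CHANNELS = (
    ("C4-A1", 100.0, "sine"),
    ("C3A2", 100.0, "sine"),
    ("EEG O2-A1", 100.0, "gaussian-noise"),
    ("EEG O1-A2", 100.0, "gaussian-noise"),
    ("EEG F4-A1", 100.0, "sine"),
    ("EEG F3-A2", 100.0, "gaussian-noise"),
    ("EEG Fpz-Cz", 100.0, "sine"),
    ("EEG Pz-Oz", 100.0, "gaussian-noise"),
    ("LOC", 50.0, "sine"),
    ("ROC", 50.0, "sine"),
    ("CHIN1", 100.0, "gaussian-noise"),
    ("LEGBEINLI", 100.0, "square"),
    ("LEGBEINRE", 100.0, "constant"),
    ("EKG", 100.0, "sine"),
    ("AIRFLOW", 10.0, "sine"),
    ("THOR RES", 10.0, "sine"),
    ("ABDO RES", 10.0, "sine"),
    ("SPO2", 1.0, "constant"),
    ("SCHNARCHEN", 10.0, "gaussian-noise"),
)


def generate_psg_like(seed: int, duration_s: float = 60.0) -> FixtureSpec:
    """A 19-channel spec shaped like a routine polysomnography montage:
    mixed sampling rates, vendor-variant labels (all resolvable by the
    bundled harmonization table), small total size."""
    rng = np.random.default_rng(seed)
    channels = []
    for label, fs, waveform in _PSG_CHANNELS:
        channels.append(
            ChannelSpec(
                label=label,
                fs=fs,
                waveform=waveform,
                amplitude=float(rng.uniform(20.0, 180.0)),
                wave_hz=float(rng.choice([0.25, 0.5, 1.0, 2.0])),
            )
        )
    return FixtureSpec(
        seed=seed,
        duration_s=duration_s,
        record_duration_s=Fraction(1),
        channels=tuple(channels),
        patient_id=f"PSG{seed:04d} X 01-JAN-1980 Synthetic_Subject",
        recording_id="Startdate 01-JAN-2019 Synthetic PSG",
        start=datetime(2019, 1, 1, 22, 0, 0),
    )
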