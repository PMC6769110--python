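# edflazy

Lazy, segment-wise access to EDF/EDF+ biosignal recordings
(polysomnography-scale), built for viewing and annotating files of any size
without ever loading them whole:

- **Bit-exact EDF header codec** (`edflazy.edf_model`) — parse/write the
  static and per-signal headers, digital→physical calibration, strict
  validation (streaming files and inconsistent headers are rejected).
- **Time-range → byte-range segment reads** (`edflazy.segment_access`) —
  record-aligned partial reads through pluggable loading strategies: local
  files and HTTP servers with range-request support. A prefetch cache keeps
  ±2 viewport widths around the current window and evicts the rest.
- **Min-max compression** (`edflazy.minmax_compress`) — reduce each channel
  to per-bucket minimum/maximum pairs at a caller-given bucket rate. At one
  bucket per pixel column this preserves the rendered image exactly while
  discarding most samples (a 500 Hz channel drawn at 40 px/s keeps 16% of
  its values).
- **Channel label harmonization** (`edflazy.harmonize_labels`) — map vendor
  label variants (`C4-A1`, `EEGC4-A1`, `EEG C4-A1`, `LEGBEINLI`, …) to
  standard names via a CSV table; unknown labels pass through flagged.
- **Pseudonymization** (`edflazy.privacy`) — replace the patient
  identification field with a generated pseudonym; persistent JSON store,
  CSV/XLSX mapping export/import, byte-identical copies when disabled.
- **JSON events** (`edflazy.events`) — timestamp-keyed event files in two
  dialects (plain label strings, or structured values with end time and
  channel), edit operations, merge/dedup, and a 30 s-epoch hypnogram
  validator.
- **Synthetic fixtures** (`edflazy.fixtures`) — deterministic generation of
  valid EDF files with exactly known samples; every test runs against these,
  no downloaded data needed.
- **CLI and static rendering** (`edflazy.cli_render`, `edflazy.cli`) —
  render a window of all channels to PNG with per-pixel-column min/max
  bars, plus header reports and utilities.

## CLI

`--input` accepts a local path or an `http(s)://` URL (range requests):

```sh
edflazy generate --seed 1 --psg --out psg.edf       # synthetic recording
edflazy info --input psg.edf                        # header report
edflazy render --input psg.edf --start 0 --duration 30 --width 1200 --out win.png
edflazy slice --input psg.edf --start 10 --duration 5 --out excerpt.edf
edflazy compress --input psg.edf --frequency 40 --out series.csv
edflazy harmonize --input psg.edf                   # label rename report
edflazy pseudonymize --input psg.edf --out anon.edf --store store.json \
    --export mapping.xlsx
edflazy events merge a.json b.json --out merged.json
edflazy events validate-hypnogram hypno.json --input psg.edf
edflazy serve-fixtures --dir . --port 8765          # range-capable server
```

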