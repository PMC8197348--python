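"""Readers and writers for the artifact's signal and tabular formats.

Formats
-------
signal files     CSV with header ``t_s,eeg_uV`` or ``t_s,cbf_ml_min``
                 (comma separator, '.' decimal, UTF-8)
session manifest YAML: animal id, sampling rate, stage table, pause
                 timestamps with assigned recovery rates, signal file names
feature tables   CSV keyed by (animal_id, pause_index, subepoch_index) with
                 the 20 feature columns plus recovery_rate and group
EDF              single-channel 16-bit European Data Format export/import
                 of the EEG trace (physical dimension fixed to µV)
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FEATURE_NAMES
from .records import CBFTrace, EEGRecord
from .synth import AnimalSession, PauseEvent, ProtocolTimeline

__all__ = [
    "write_session",
    "read_session",
    "write_feature_table",
    "read_feature_table",
    "feature_table_columns",
    "write_edf",
    "read_edf",
]

_KEY_COLUMNS = ("animal_id", "pause_index", "subepoch_index")
_LABEL_COLUMNS = ("recovery_rate", "group")


def feature_table_columns() -> list[str]:
    return [*_KEY_COLUMNS, *FEATURE_NAMES, *_LABEL_COLUMNS]


# ---------------------------------------------------------------------------
# delimited-text signals


def _write_signal_csv(path: Path, times: np.ndarray, values: np.ndarray, value_header: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"t_s,{value_header}\n")
        for t, v in zip(times, values):
            fh.write(f"{t:.6f},{v:.6f}\n")


def _read_signal_csv(path: Path, value_header: str) -> tuple[np.ndarray, np.ndarray]:
    if not Path(path).exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    df = pd.read_csv(path)
    expected = ["t_s", value_header]
    if list(df.columns) != expected:
        raise ValueError(
            f"malformed header in {path}: expected {expected}, got {list(df.columns)}"
        )
    return df["t_s"].to_numpy(float), df[value_header].to_numpy(float)


# ---------------------------------------------------------------------------
# sessions


def write_session(session: AnimalSession, directory: str | Path) -> Path:
    """Write one session (manifest + EEG + CBF text files); returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = session.animal_id
    eeg_file = f"{stem}_eeg.csv"
    cbf_file = f"{stem}_cbf.csv"
    _write_signal_csv(directory / eeg_file, session.eeg.times, session.eeg.samples, "eeg_uV")
    cbf_times = session.cbf.t0 + np.arange(session.cbf.samples.size) / session.cbf.fs
    _write_signal_csv(directory / cbf_file, cbf_times, session.cbf.samples, "cbf_ml_min")
    manifest = {
        "animal_id": session.animal_id,
        "fs_hz": float(session.eeg.fs),
        "eeg_file": eeg_file,
        "cbf_file": cbf_file,
        "cbf_baseline_ml_min": float(session.cbf.baseline_value),
        "rosc_stage": session.rosc_stage,
        "stages": [
            {"kind": k, "duration_s": float(d)} for k, d in session.timeline.stages
        ],
        "pause_duration_s": float(session.timeline.pause_duration),
        "bls_cycles": session.timeline.bls_cycles,
        "max_acls_cycles": session.timeline.max_acls_cycles,
        "pauses": [
            {
                "index": p.index,
                "start_s": float(p.start_s),
                "recovery_rate_pct": float(p.recovery_rate),
                "group": int(p.group),
            }
            for p in session.pauses
        ],
    }
    manifest_path = directory / f"{stem}_manifest.yaml"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_session(manifest_path: str | Path) -> AnimalSession:
    """Load a session from its manifest; signals are re-attached with the
    manifest's sampling rate and pause annotations."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path, encoding="utf-8") as fh:
        m = yaml.safe_load(fh)
    for key in ("animal_id", "fs_hz", "eeg_file", "cbf_file", "stages", "pauses"):
        if key not in m:
            raise ValueError(f"manifest {manifest_path} missing field {key!r}")
    fs = float(m["fs_hz"])
    directory = manifest_path.parent
    t_eeg, eeg_vals = _read_signal_csv(directory / m["eeg_file"], "eeg_uV")
    _, cbf_vals = _read_signal_csv(directory / m["cbf_file"], "cbf_ml_min")
    if t_eeg.size >= 2:
        fs_file = 1.0 / float(np.median(np.diff(t_eeg)))
        if abs(fs_file - fs) > 0.01 * fs:
            raise ValueError(
                f"fs mismatch in {m['eeg_file']}: manifest says {fs} Hz, "
                f"timestamps imply {fs_file:.3f} Hz"
            )
    timeline = ProtocolTimeline(
        [(s["kind"], float(s["duration_s"])) for s in m["stages"]],
        pause_duration=float(m.get("pause_duration_s", 3.0)),
        bls_cycles=int(m.get("bls_cycles", 4)),
        max_acls_cycles=int(m.get("max_acls_cycles", 10)),
    )
    annotations = [(k, s, e) for k, s, e in timeline.stage_starts()]
    eeg = EEGRecord(eeg_vals, fs, annotations=annotations)
    cbf = CBFTrace(cbf_vals, fs, baseline_value=float(m["cbf_baseline_ml_min"]))
    pauses = [
        PauseEvent(
            int(p["index"]), float(p["start_s"]), float(p["recovery_rate_pct"]), int(p["group"])
        )
        for p in m["pauses"]
    ]
    return AnimalSession(m["animal_id"], timeline, eeg, cbf, pauses, m.get("rosc_stage"))


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV with a stable column order."""
    cols = feature_table_columns()
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if table.duplicated(subset=list(_KEY_COLUMNS)).any():
        raise ValueError("duplicate (animal_id, pause_index, subepoch_index) keys")
    # %.17g round-trips IEEE doubles exactly
    table[cols].to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table, validating completeness and numeric content."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path)
    cols = feature_table_columns()
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} missing columns: {missing}")
    df = df[cols]
    if df.duplicated(subset=list(_KEY_COLUMNS)).any():
        raise ValueError("duplicate (animal_id, pause_index, subepoch_index) keys")
    numeric = [*FEATURE_NAMES, *_LABEL_COLUMNS]
    for col in numeric:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any() and len(df):
            raise ValueError(f"non-numeric or missing value in column {col!r}")
        df[col] = values.astype(int if col == "group" else float)
    return df


# ---------------------------------------------------------------------------
# EDF (single EEG channel, 16-bit)


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii")[:width]
    return raw + b" " * (width - len(raw))


def write_edf(record: EEGRecord, path: str | Path, label: str = "EEG Fp") -> None:
    """Write the EEG channel as a minimal single-signal EDF file.

    One data record per second; the final record is zero-padded when the
    trace length is not a whole number of seconds. Physical dimension is µV.
    """
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s data record
    x = record.samples
    n_records = int(np.ceil(x.size / spr)) if x.size else 0
    padded = np.zeros(n_records * spr)
    padded[: x.size] = x
    phys_max = float(np.max(np.abs(padded))) if padded.size else 1.0
    if phys_max <= 0:
        phys_max = 1.0
    dig_min, dig_max = -32768, 32767
    scale = dig_max / phys_max
    digital = np.clip(np.round(padded * scale), dig_min, dig_max).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad("synthetic swine", 80),
            _pad("eegcbf export", 80),
            _pad("01.01.21", 8),
            _pad("00.00.00", 8),
            _pad(str(256 + 256), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad("1", 4),
        ]
    )
    signal_header = b"".join(
        [
            _pad(label, 16),
            _pad("AgAgCl electrode", 80),
            _pad("uV", 8),
            _pad(f"{-phys_max:.6g}"[:8], 8),
            _pad(f"{phys_max:.6g}"[:8], 8),
            _pad(str(dig_min), 8),
            _pad(str(dig_max), 8),
            _pad("BP:0.5-47Hz", 80),
            _pad(str(spr), 8),
            _pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        fh.write(digital.tobytes())


def read_edf(path: str | Path) -> EEGRecord:
    """Read a single-channel EDF file written by :func:`write_edf`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise ValueError("truncated EDF header")
        n_records = int(header[236:244].decode("ascii").strip())
        record_dur = float(header[244:252].decode("ascii").strip())
        n_signals = int(header[252:256].decode("ascii").strip())
        if n_signals != 1:
            raise ValueError(f"expected a single-channel EDF, got {n_signals} signals")
        sig = fh.read(256 * n_signals)
        # field offsets: label 0, transducer 16, dimension 96, then the
        # physical/digital ranges
        phys_min = float(sig[104:112].decode("ascii").strip())
        phys_max = float(sig[112:120].decode("ascii").strip())
        dig_min = int(sig[120:128].decode("ascii").strip())
        dig_max = int(sig[128:136].decode("ascii").strip())
        spr = int(sig[216:224].decode("ascii").strip())
        payload = fh.read(2 * spr * n_records)
    digital = np.frombuffer(payload, dtype="<i2").astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    physical = phys_min + (digital - dig_min) * gain
    fs = spr / record_dur
    return EEGRecord(physical, fs)
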