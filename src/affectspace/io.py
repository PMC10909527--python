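"""Reading and writing of trial tables and raw-signal bundles (CSV/JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import REQUIRED_COLUMNS, TrialTableError, validate_trial_table
from .signals import SignalRecording

__all__ = ["read_trial_table", "write_trial_table", "write_signals", "read_signals"]


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a validated trial table as UTF-8 CSV with a header row."""
    validate_trial_table(table)
    table.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table CSV.

    Required columns are type-checked; extra columns are preserved as
    passthrough metadata.  Errors name the offending column or rows.
    """
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableError(f"{path}: missing required column(s): {missing}")
    numeric = ["valence", "arousal", "pupil", "scr", "hr", "brightness"]
    for col in numeric:
        try:
            table[col] = pd.to_numeric(table[col])
        except (ValueError, TypeError) as exc:
            raise TrialTableError(f"{path}: column {col!r} is not numeric: {exc}") from exc
    validate_trial_table(table)
    return table


def write_signals(recordings: list[SignalRecording], outdir) -> None:
    """Write one two-column (time_s, value) CSV per trial recording plus a
    JSON event manifest; invalid samples are written as empty values."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, rec in enumerate(recordings):
        trial_id = rec.events[0][0] if rec.events else f"rec{i}"
        fname = f"{trial_id}_{rec.modality}.csv"
        values = np.where(rec.valid, rec.values, np.nan)
        pd.DataFrame({"time_s": rec.times, "value": values}).to_csv(
            outdir / fname, index=False
        )
        manifest.append(
            {
                "file": fname,
                "modality": rec.modality,
                "sampling_rate": rec.sampling_rate,
                "events": [[tid, onset] for tid, onset in rec.events],
                "meta": rec.meta,
            }
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_signals(indir) -> list[SignalRecording]:
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    recordings = []
    for entry in manifest:
        df = pd.read_csv(indir / entry["file"])
        values = df["value"].to_numpy(dtype=float)
        valid = np.isfinite(values)
        recordings.append(
            SignalRecording(
                modality=entry["modality"],
                sampling_rate=float(entry["sampling_rate"]),
                times=df["time_s"].to_numpy(dtype=float),
                values=np.where(valid, values, 0.0),
                valid=valid,
                events=[(tid, float(onset)) for tid, onset in entry["events"]],
                meta=entry.get("meta", {}),
            )
        )
    return recordings
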