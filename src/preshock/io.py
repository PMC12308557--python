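"""CSV readers and writers for records, cohorts and feature tables.

Record format: one CSV per record with columns ``time_s, voltage_mV``,
plus a manifest CSV (``record_id, label, fs, n_samples, path``).  A
synthetic cohort additionally gets a ground-truth sidecar CSV per record.
All files are UTF-8, comma-separated, header row mandatory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FEATURE_UNITS, BandConfig
from .records import ECGRecord, LABEL_UNKNOWN, VALID_LABELS

MANIFEST_NAME = "manifest.csv"


def write_records(records, out_dir, truths=None) -> Path:
    """Write records (and optional ground truths) plus a manifest.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, record in enumerate(records):
        fname = f"{record.record_id}.csv"
        df = pd.DataFrame({"time_s": record.times, "voltage_mV": record.samples})
        df.to_csv(out_dir / fname, index=False)
        rows.append(
            {
                "record_id": record.record_id,
                "label": record.label,
                "fs": record.fs,
                "n_samples": record.n_samples,
                "path": fname,
            }
        )
        if truths is not None:
            truth = truths[i]
            pd.DataFrame(
                {
                    "r_peak_time_s": truth.r_peak_times,
                    "amplitude_mV": truth.beat_amplitudes,
                    "extremum_gap_ms": truth.beat_extremum_gaps,
                    "noise_power_mV2": np.full(truth.n_beats, truth.noise_power),
                }
            ).to_csv(out_dir / f"{record.record_id}.truth.csv", index=False)
    manifest = out_dir / MANIFEST_NAME
    pd.DataFrame(rows, columns=["record_id", "label", "fs", "n_samples", "path"]).to_csv(
        manifest, index=False
    )
    return manifest


def read_records(manifest_path) -> list[ECGRecord]:
    """Load all records listed in a manifest CSV.

    Raises
    ------
    ValueError
        On missing sampling-rate metadata or non-numeric samples (the
        offending record and row are named).
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        return []
    if "fs" not in manifest.columns or manifest["fs"].isna().any():
        raise ValueError(f"{manifest_path}: every record needs sampling-rate metadata (fs)")
    records = []
    for _, row in manifest.iterrows():
        path = manifest_path.parent / row["path"]
        df = pd.read_csv(path)
        voltage = pd.to_numeric(df["voltage_mV"], errors="coerce")
        bad = np.flatnonzero(voltage.isna().to_numpy())
        if bad.size:
            raise ValueError(
                f"{path}: non-numeric voltage at data row {bad[0]} "
                f"(value {df['voltage_mV'].iloc[bad[0]]!r})"
            )
        label = row.get("label", LABEL_UNKNOWN)
        if pd.isna(label) or label not in VALID_LABELS:
            label = LABEL_UNKNOWN
        records.append(
            ECGRecord(
                samples=voltage.to_numpy(dtype=float),
                fs=float(row["fs"]),
                record_id=str(row["record_id"]),
                label=label,
            )
        )
    return records


def write_feature_table(table: pd.DataFrame, path, bands: BandConfig | None = None) -> None:
    """Feature table CSV with units in the header + band-config JSON sidecar."""
    path = Path(path)
    renamed = table.rename(
        columns={name: f"{name}_{FEATURE_UNITS[name]}" for name in FEATURE_NAMES}
    )
    renamed.to_csv(path)
    bands = bands or BandConfig()
    sidecar = path.with_suffix(".bands.json")
    sidecar.write_text(
        json.dumps({"total": bands.total, "lf": bands.lf, "hf": bands.hf}, sort_keys=True)
        + "\n"
    )


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table CSV written by :func:`write_feature_table`."""
    table = pd.read_csv(path, index_col=0)
    strip = {f"{name}_{FEATURE_UNITS[name]}": name for name in FEATURE_NAMES}
    return table.rename(columns=strip)
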