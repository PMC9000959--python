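"""Readers and writers for the package's CSV schemas.

Dialect: comma-separated UTF-8 with ``.`` decimals; metadata rides in
``# key: value`` comment lines before the header. Every artifact written by
the CLI carries provenance metadata (package version, seed, config hash).
"""
from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import MeasurementTable
from .kinetics import DoseResponse, TimeCourse

__all__ = [
    "read_measurement_csv",
    "write_measurement_csv",
    "write_timecourse_csv",
    "read_timecourse_csv",
    "write_dose_response_csv",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _read_with_metadata(path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
        else:
            lines.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(lines)))
    return df, meta


def _write_with_metadata(df: pd.DataFrame, path, metadata: dict | None) -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_measurement_csv(path) -> MeasurementTable:
    """Read a measurement table (columns time, dose_<species>..., value,
    replicate); validates the schema and returns a MeasurementTable."""
    df, meta = _read_with_metadata(path)
    missing = [c for c in MeasurementTable.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    background = float(meta.get("background", 0.0))
    subtracted = meta.get("background_subtracted", "true").lower() != "false"
    return MeasurementTable(
        df, strain_id=meta.get("strain_id"), background=background,
        background_subtracted=subtracted,
    )


def write_measurement_csv(table: MeasurementTable, path,
                          metadata: dict | None = None) -> None:
    meta = {
        "schema": "measurement/v1",
        "strain_id": table.strain_id or "",
        "background": table.background,
        "background_subtracted": str(table.background_subtracted).lower(),
    }
    meta.update(metadata or {})
    _write_with_metadata(table.data, path, meta)


def write_timecourse_csv(tc: TimeCourse, path, metadata: dict | None = None) -> None:
    df = pd.DataFrame({"t_h": tc.t})
    for i, label in enumerate(tc.labels):
        df[label] = tc.y[i]
    meta = {"schema": "timecourse/v1"}
    meta.update(metadata or {})
    _write_with_metadata(df, path, meta)


def read_timecourse_csv(path) -> TimeCourse:
    df, _ = _read_with_metadata(path)
    labels = [c for c in df.columns if c != "t_h"]
    y = np.vstack([df[c].to_numpy(dtype=float) for c in labels])
    return TimeCourse(df["t_h"].to_numpy(dtype=float), y, labels)


def write_dose_response_csv(dr: DoseResponse, path,
                            metadata: dict | None = None) -> None:
    df = pd.DataFrame({"dose_nM": dr.dose, "value": dr.response})
    meta = {"schema": "dose_response/v1", "read_time_h": dr.read_time}
    meta.update(metadata or {})
    _write_with_metadata(df, path, meta)
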