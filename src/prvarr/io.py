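"""Plain-text I/O: two-column waveform CSV, segment CSV, feature CSV, models.

Waveform records travel as two-column CSV (``time_s``, ``pressure``) with
an optional one-column annotation CSV of peak sample indices.  Segments
serialise their three per-beat series as JSON lists inside CSV cells, so
a segment file stays a single flat table.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .types import ABPRecord, PRVSegment

__all__ = [
    "read_record_csv",
    "write_record_csv",
    "read_segments_csv",
    "write_segments_csv",
    "read_features_csv",
    "write_features_csv",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


def write_record_csv(record: ABPRecord, path, annotations_path=None) -> None:
    """Write a waveform as ``time_s,pressure``; annotations go to a side file."""
    df = pd.DataFrame({"time_s": record.times, "pressure": record.samples})
    df.to_csv(path, index=False, float_format="%.9g")
    if annotations_path is not None and record.annotations is not None:
        pd.DataFrame({"peak_index": record.annotations}).to_csv(
            annotations_path, index=False
        )


def read_record_csv(path, fs: float | None = None, annotations_path=None) -> ABPRecord:
    """Read a two-column waveform CSV; fs is inferred from the time column
    unless given explicitly."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("record CSV needs two columns: time (s) and pressure")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    if fs is None:
        dt = np.median(np.diff(t))
        if not dt > 0:
            raise ValueError("cannot infer sampling rate from the time column")
        fs = 1.0 / dt
    ann = None
    if annotations_path is not None and Path(annotations_path).exists():
        ann = pd.read_csv(annotations_path).iloc[:, 0].to_numpy(dtype=np.int64)
    return ABPRecord(samples=x, fs=float(fs), annotations=ann, meta={"path": str(path)})


def write_segments_csv(segments: list[PRVSegment], path) -> None:
    rows = [
        {
            "source": s.source,
            "label": s.label if s.label is not None else "",
            "prv_json": json.dumps([round(v, 9) for v in s.prv.tolist()]),
            "ppi_json": json.dumps([round(v, 9) for v in s.ppi.tolist()]),
            "apm_json": json.dumps([round(v, 9) for v in s.apm.tolist()]),
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_segments_csv(path) -> list[PRVSegment]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        label = row["label"]
        label = int(label) if str(label) not in ("", "nan") else None
        out.append(
            PRVSegment(
                prv=np.array(json.loads(row["prv_json"])),
                ppi=np.array(json.loads(row["ppi_json"])),
                apm=np.array(json.loads(row["apm_json"])),
                label=label,
                source=str(row["source"]),
            )
        )
    return out


def write_features_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV is missing columns: {missing}")
    return df


def save_model(model, path, extra: dict | None = None) -> None:
    """Serialise a trained model with its schema, seed and config."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": model.kind,
        "seed": model.seed,
        "feature_names": model.feature_names,
        "config": model.config,
        "model": model,
    }
    if extra:
        payload.update(extra)
    joblib.dump(payload, path)


def load_model(path):
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    return payload["model"]
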