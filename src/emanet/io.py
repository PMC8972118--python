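"""Plain-text round-tripping of every artifact the pipeline produces.

Formats: long-format EMA CSV (empty cell = missing), raw-accelerometer CSV
with a JSON sidecar for the sampling rate, analysis-table CSV, network
JSON and edge-list CSV, centrality CSV, permutation-result JSON/CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .actigraphy import RawAccelSignal
from .preprocess import AnalysisTable
from .synthetic import EmaDataset

__all__ = [
    "write_ema_csv",
    "read_ema_csv",
    "write_accel_csv",
    "read_accel_csv",
    "write_analysis_csv",
    "read_analysis_csv",
    "write_permutation_csv",
]

META_COLS = ["subject_id", "group", "day", "beep", "timestamp"]


def write_ema_csv(dataset: EmaDataset, path) -> None:
    df = dataset.data.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df[META_COLS + list(dataset.node_labels)].to_csv(path, index=False)


def read_ema_csv(path, node_labels=None) -> EmaDataset:
    df = pd.read_csv(path)
    missing = [c for c in META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"EMA CSV lacks columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if node_labels is None:
        node_labels = tuple(c for c in df.columns if c not in META_COLS)
    return EmaDataset(data=df, node_labels=tuple(node_labels), provenance="file")


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".meta.json")


def write_accel_csv(signal: RawAccelSignal, path) -> None:
    pd.DataFrame(
        {
            "timestamp": signal.timestamps,
            "x_mg": signal.x,
            "y_mg": signal.y,
            "z_mg": signal.z,
        }
    ).to_csv(path, index=False)
    with open(_sidecar(path), "w") as fh:
        json.dump({"sampling_rate": signal.sampling_rate}, fh)
        fh.write("\n")


def read_accel_csv(path) -> RawAccelSignal:
    df = pd.read_csv(path)
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    return RawAccelSignal(
        timestamps=df["timestamp"].to_numpy(),
        x=df["x_mg"].to_numpy(),
        y=df["y_mg"].to_numpy(),
        z=df["z_mg"].to_numpy(),
        sampling_rate=float(meta["sampling_rate"]),
    )


def write_analysis_csv(table: AnalysisTable, path) -> None:
    df = table.data.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df[META_COLS + list(table.node_labels)].to_csv(path, index=False)


def read_analysis_csv(path, node_labels=None) -> AnalysisTable:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if node_labels is None:
        node_labels = tuple(c for c in df.columns if c not in META_COLS)
    return AnalysisTable(data=df, node_labels=tuple(node_labels))


def write_permutation_csv(result, path) -> None:
    cols = ["statistic", "kind", "observed", "p"]
    df = result.table[cols].copy()
    df["n_perm"] = result.n_permutations
    df.to_csv(path, index=False)
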