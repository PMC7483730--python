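"""Plain-text serialization helpers (TSV + JSON sidecars).

TSV is the canonical interchange for every intermediate: partitions are
L x N integer tables, matrices are N x N float tables, metric tables are
region-indexed data frames.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_partition",
    "read_partition",
    "write_matrix",
    "read_matrix",
    "write_metric_table",
    "read_metric_table",
    "write_json",
    "read_json",
]


def write_partition(labels: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(labels, dtype=int), fmt="%d", delimiter="\t")


def read_partition(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=int, delimiter="\t", ndmin=2)


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.8g", delimiter="\t")


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_metric_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, float_format="%.8g")


def read_metric_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
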