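"""File I/O for the package's plain-text interchange formats.

Conventions:

* **Expression matrix** — TSV, first row sample ids, first column feature
  ids (features x samples), numeric values.
* **Sample table** — CSV with columns ``sample_id, group, zap70, igvh,
  ttft_days, event``; ``group`` is one of ``CLL``, ``control_B``,
  ``activated_B``.
* **Ct table** — CSV with columns ``sample_id, target, replicate, ct``.
* **Ground truth / provenance / manifests** — JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("CLL", "control_B", "activated_B")
SAMPLE_COLUMNS = ["group", "zap70", "igvh", "ttft_days", "event"]


def read_matrix(path) -> pd.DataFrame:
    """Read a features-by-samples expression matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {path}: {dupes}")
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_table(path) -> pd.DataFrame:
    """Read a sample annotation table (CSV, indexed by ``sample_id``)."""
    df = pd.read_csv(path, index_col="sample_id")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table {path} missing columns: {missing}")
    bad = set(df["group"].unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels in {path}: {sorted(bad)}")
    return df


def write_sample_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index_label="sample_id")


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"sample_id", "target", "replicate", "ct"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"Ct table {path} missing columns: {sorted(missing)}")
    return df


def write_ct_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n"
    )


def read_json(path):
    return json.loads(Path(path).read_text())
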