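"""Tab-separated and JSON readers/writers with deterministic formatting.

All tables are written with a fixed column order, '\\n' line endings and a
10-significant-digit float format so that repeated runs under the same seed
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT,
              lineterminator="\n")


def read_counts(path) -> pd.DataFrame:
    """Counts TSV: first column probe_id, remaining columns sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe_id"
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    counts.to_csv(path, sep="\t", lineterminator="\n")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "chemical", "concentration_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return df


def read_plate(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"well_id", "chemical", "concentration_uM", "role", "absorbance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    return df


def read_fold_changes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or "log2fc" not in df.columns:
        raise ValueError("fold-change table needs gene and log2fc columns")
    return df


def read_evidence_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
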