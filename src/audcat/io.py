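"""CSV reading/writing for trial tables and result tables.

All files are plain comma-separated UTF-8 with a header row and '.' decimals.
A single leading comment line carries provenance metadata (root seed, config
hash), so a pipeline rerun from the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .synthetic_data import CATEGORIZATION_COLUMNS, DISCRIMINATION_COLUMNS

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "read_categorization",
    "read_discrimination",
    "responded_only",
]

_BOOL_COLUMNS = {"standard_first", "judged_comparison_higher", "correct", "extrapolated"}


def config_hash(config: dict) -> str:
    """Short stable digest of a config mapping (order-insensitive)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if meta:
            pairs = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
            fh.write(f"# audcat {pairs}\n")
        df.to_csv(fh, index=False)


def read_table(path, required_columns=None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if required_columns is not None:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    for col in _BOOL_COLUMNS & set(df.columns):
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return df


def read_categorization(path) -> pd.DataFrame:
    df = read_table(path, CATEGORIZATION_COLUMNS)
    df["condition"] = df["condition"].astype(float)
    return df


def read_discrimination(path) -> pd.DataFrame:
    return read_table(path, DISCRIMINATION_COLUMNS)


def responded_only(trials: pd.DataFrame) -> pd.DataFrame:
    """Keep only trials in which a response was made (choice A or B)."""
    return trials[trials["choice"].isin(["A", "B"])]
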