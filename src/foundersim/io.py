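"""Tidy CSV output of experiment tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["RESULT_COLUMNS", "write_results", "read_results"]

#: Fixed column order of every results CSV.
RESULT_COLUMNS = [
    "preset", "replicate", "seed", "y", "K", "r", "M", "F", "delta", "c",
    "bank", "FST", "FSTQ", "H_T", "H_S", "census_1", "census_2",
    "extinct_flag",
]


def write_results(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy results table to CSV with the fixed header.

    Floats keep full round-trip precision, so reading the file back yields
    the in-memory table.
    """
    if table.empty:
        raise ValueError("refusing to write an empty results table")
    missing = [col for col in RESULT_COLUMNS if col not in table.columns]
    if missing:
        raise ValueError(f"results table is missing columns: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[RESULT_COLUMNS].to_csv(path, index=False, float_format="%.17g")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results`."""
    return pd.read_csv(path)
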