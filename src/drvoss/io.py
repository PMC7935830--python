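"""NONMEM-style CSV persistence for simulated datasets.

Columns: ID, REP, TAD, DV, CPRED, AMT, II, SEX, CYP3A5, SLCO3A1, CL, V, KA,
AUC24.  Missing numeric values are written as "." (the NONMEM convention);
floats are written with 6 significant digits, so a round-trip is lossless to
that precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DATASET_COLUMNS", "write_dataset", "read_dataset"]

DATASET_COLUMNS = [
    "ID", "REP", "TAD", "DV", "CPRED", "AMT", "II",
    "SEX", "CYP3A5", "SLCO3A1", "CL", "V", "KA", "AUC24",
]

_INT_COLUMNS = ("ID", "REP", "SEX", "CYP3A5", "SLCO3A1")


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Write a simulated dataset to NONMEM-style CSV."""
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing columns: {missing}")
    out = df[DATASET_COLUMNS].copy()
    with Path(path).open("w") as fh:
        fh.write(",".join(DATASET_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            cells = []
            for col, val in zip(DATASET_COLUMNS, row):
                if val is None or (isinstance(val, float) and np.isnan(val)):
                    cells.append(".")
                elif col in _INT_COLUMNS:
                    cells.append(str(int(val)))
                else:
                    cells.append(f"{float(val):.6g}")
            fh.write(",".join(cells) + "\n")


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read a NONMEM-style CSV written by :func:`write_dataset`."""
    df = pd.read_csv(path, na_values=["."], keep_default_na=False)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"file lacks expected columns: {missing}")
    for col in _INT_COLUMNS:
        if df[col].notna().all():
            df[col] = df[col].astype(int)
    return df
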