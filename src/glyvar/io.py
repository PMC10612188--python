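"""Delimited-file I/O for the visit and patient tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

VISIT_COLUMNS = ["patient_id", "month", "hba1c"]
FLOAT_FORMAT = "%.12g"


def read_visits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(VISIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"visits file {path} missing columns {sorted(missing)}")
    return df


def read_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "arm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"patients file {path} missing columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV writer (fixed float format, LF newlines)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
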