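"""Reading and writing the pipeline's delimited-text tables.

Two inputs drive the pipeline:

* measurements — one row per tumor per platform with columns
  ``case_id``, ``platform_id``, ``score`` (positive continuous intensity,
  arbitrary units);
* clinical — one row per case with columns ``case_id``, ``time_months``,
  ``event`` plus optional categorical covariates and an optional
  ``chromogen_percent`` column (integers in {0} or 1..95).

Both are tab-delimited with a header row; any whitespace/comma delimiter
pandas can sniff is accepted on input.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_measurements", "read_clinical", "write_table"]

_RESERVED_CLINICAL = {"case_id", "time_months", "event", "chromogen_percent"}


def _read(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a measurements table.

    Malformed rows are reported with their file line number (header = line
    1). Scores must be strictly positive; a (case, platform) pair may
    appear only once.
    """
    df = _read(path)
    missing = {"case_id", "platform_id", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"measurements table missing column(s): {sorted(missing)}")
    score = pd.to_numeric(df["score"], errors="coerce")
    bad = score.isna() | (score <= 0)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        raise ValueError(
            f"nonpositive or unparseable score at line(s) {lines[:10]} of {path}"
        )
    df["score"] = score.astype(float)
    dup = df.duplicated(subset=["case_id", "platform_id"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate (case, platform) pair: ({row['case_id']!r}, {row['platform_id']!r})"
        )
    return df


def read_clinical(path) -> pd.DataFrame:
    """Read and validate a clinical table.

    Follow-up times must be nonnegative, event flags 0/1, and
    ``chromogen_percent`` (if present) 0 or an integer-valued percentage in
    [1, 95]. Unknown covariate columns pass through as categories.
    """
    df = _read(path)
    missing = {"case_id", "time_months", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing column(s): {sorted(missing)}")
    t = pd.to_numeric(df["time_months"], errors="coerce")
    if t.isna().any() or (t < 0).any():
        lines = (df.index[t.isna() | (t < 0)] + 2).tolist()
        raise ValueError(f"negative or unparseable time_months at line(s) {lines[:10]}")
    df["time_months"] = t.astype(float)
    ev = pd.to_numeric(df["event"], errors="coerce")
    if not ev.isin([0, 1]).all():
        lines = (df.index[~ev.isin([0, 1])] + 2).tolist()
        raise ValueError(f"event flag outside {{0, 1}} at line(s) {lines[:10]}")
    df["event"] = ev.astype(int)
    if df["case_id"].duplicated().any():
        case = df.loc[df["case_id"].duplicated(), "case_id"].iloc[0]
        raise ValueError(f"duplicate case_id in clinical table: {case!r}")
    if "chromogen_percent" in df.columns:
        c = pd.to_numeric(df["chromogen_percent"], errors="coerce")
        ok = (c == 0) | ((c >= 1) & (c <= 95))
        ok &= np.isclose(c % 1, 0) | c.isna()
        valid = ok | c.isna()
        if not valid.all():
            lines = (df.index[~valid] + 2).tolist()
            raise ValueError(
                "chromogen_percent outside {0} u [1, 95] at line(s) "
                f"{lines[:10]}"
            )
        df["chromogen_percent"] = c
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as tab-delimited text with a header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path
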