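"""Reading and writing the package's delimited-text formats.

Event files are plain CSV with header ``pig_id,day,visit,otv_s,fiv_g,bw_kg``;
truth files carry the simulator's per-animal parameters.  Missing fields are
legal (they model incomplete feeder records and are handled by QC); tokens
that fail to parse as numbers are reported with their row numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import EVENT_COLUMNS, TRUTH_COLUMNS

_FLOAT_FMT = "%.6f"


class MalformedRowError(ValueError):
    """A data row contained a token that is not a number."""

    def __init__(self, path, rows):
        self.rows = list(rows)
        preview = ", ".join(str(r) for r in self.rows[:10])
        more = "" if len(self.rows) <= 10 else f" (+{len(self.rows) - 10} more)"
        super().__init__(
            f"{path}: malformed value(s) in file row(s) {preview}{more}")


def write_events(events: pd.DataFrame, path) -> None:
    """Write a visit table to CSV at fixed (1e-6) precision."""
    out = events[EVENT_COLUMNS]
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events(path) -> pd.DataFrame:
    """Read a visit table, validating the header and every numeric token.

    Raises :class:`MalformedRowError` naming the 1-based file rows (header
    counted as row 1) of any unparseable values.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing_cols = [c for c in EVENT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing column(s) {missing_cols}")
    parsed = {}
    bad_rows: set[int] = set()
    for col in EVENT_COLUMNS:
        values = pd.to_numeric(raw[col], errors="coerce")
        malformed = values.isna() & raw[col].notna()
        bad_rows.update((np.flatnonzero(malformed) + 2).tolist())
        parsed[col] = values
    if bad_rows:
        raise MalformedRowError(path, sorted(bad_rows))
    df = pd.DataFrame(parsed)
    for col in ("pig_id", "day", "visit"):
        if df[col].isna().any():
            raise ValueError(f"{path}: missing values in key column {col!r}")
        df[col] = df[col].astype(np.int64)
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    truth[TRUTH_COLUMNS].to_csv(path, index=False, float_format="%.9f")


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing_cols = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing column(s) {missing_cols}")
    df["pig_id"] = df["pig_id"].astype(np.int64)
    return df
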