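"""Reading and writing track tables and run configuration.

Tracks are exchanged as delimited text with a header ``track_id,t,x,y``
(times in seconds, positions in micrometers). Rows may arrive unsorted
within a track; they are sorted by time, but duplicate ``(track_id, t)``
rows are rejected. Configuration round-trips through YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .empirical import validate_tracks

__all__ = ["read_tracks", "write_tracks", "load_config", "save_config"]

REQUIRED_COLUMNS = ["track_id", "t", "x", "y"]


def read_tracks(path) -> pd.DataFrame:
    """Read and validate a track table from a delimited text file."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("t", "x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric {col!r} at line(s) {lines}")
        df[col] = pd.to_numeric(df[col])
    if df[REQUIRED_COLUMNS].isna().any().any():
        raise ValueError(f"{path}: missing values in required columns")
    dup = df.duplicated(subset=["track_id", "t"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()[:5]
        raise ValueError(f"{path}: duplicate (track_id, t) rows at line(s) {lines}")
    df = df.sort_values(["track_id", "t"], kind="stable").reset_index(drop=True)
    validate_tracks(df)
    return df[REQUIRED_COLUMNS + [c for c in df.columns if c not in REQUIRED_COLUMNS]]


def write_tracks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
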