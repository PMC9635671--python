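"""Reading and writing the canonical long-format tables.

Curve table (CSV): columns ``plate_id, row, col, cycle, time_h, cells``;
rows and columns are 0-based plate coordinates, ``cycle`` is 1-based with 0
reserved for the stress-free preculture measurement.  Layout table (CSV):
columns ``plate_id, row, col, role, strain_id, replicate`` with role in
{strain, reference, empty}.  All tables written by aletrack start with a
``# aletrack-schema=1`` comment line; readers accept files with or without
it.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import RecordError, SchemaError

SCHEMA_HEADER = "# aletrack-schema=1"

CURVE_COLUMNS = ["plate_id", "row", "col", "cycle", "time_h", "cells"]
LAYOUT_COLUMNS = ["plate_id", "row", "col", "role", "strain_id", "replicate"]
LAYOUT_ROLES = {"strain", "reference", "empty"}


def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a result table as CSV with the schema version header."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def _read_csv(path: str, required: list[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} {path}: missing required columns {missing}")
    return df


def read_curve_table(path: str) -> pd.DataFrame:
    """Read and validate a long-format curve table.

    Checks the schema, rejects duplicated ``(plate_id, row, col, cycle,
    time_h)`` rows (reporting data-row numbers), and verifies that within
    every colony-cycle the time points are distinct.  Returns the table
    sorted by colony, cycle and time.
    """
    df = _read_csv(path, CURVE_COLUMNS, "curve table")
    bad = df[CURVE_COLUMNS[:5]].isna().any(axis=1) | df["cells"].isna()
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 1)[:5].tolist()
        raise RecordError(f"curve table {path}: malformed rows at data rows {rows}")
    if (df["cells"] <= 0).any():
        rows = (np.flatnonzero((df["cells"] <= 0).to_numpy()) + 1)[:5].tolist()
        raise RecordError(f"curve table {path}: non-positive cells at data rows {rows}")
    key = ["plate_id", "row", "col", "cycle", "time_h"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        rows = (np.flatnonzero(dup.to_numpy()) + 1)[:5].tolist()
        raise RecordError(
            f"curve table {path}: duplicated (plate,row,col,cycle,time) at "
            f"data rows {rows} (plate {first['plate_id']}, row {first['row']}, "
            f"col {first['col']}, cycle {first['cycle']}, t={first['time_h']})")
    df = df.sort_values(key, kind="stable").reset_index(drop=True)
    # after sorting, strictly increasing time within each colony-cycle is
    # guaranteed unless times repeat, which the duplicate check caught
    return df


def read_layout_table(path: str) -> pd.DataFrame:
    """Read and validate a plate-layout table."""
    df = _read_csv(path, LAYOUT_COLUMNS, "layout table")
    df["strain_id"] = df["strain_id"].fillna("")
    roles = set(df["role"].unique())
    if not roles <= LAYOUT_ROLES:
        raise SchemaError(
            f"layout table {path}: unknown roles {sorted(roles - LAYOUT_ROLES)}")
    dup = df.duplicated(subset=["plate_id", "row", "col"], keep=False)
    if dup.any():
        rows = (np.flatnonzero(dup.to_numpy()) + 1)[:5].tolist()
        raise RecordError(
            f"layout table {path}: duplicated positions at data rows {rows}")
    return df


def iter_curves(curve_df: pd.DataFrame):
    """Yield ``((plate_id, row, col, cycle), times, cells)`` per colony-cycle."""
    for key, grp in curve_df.groupby(["plate_id", "row", "col", "cycle"],
                                     sort=True):
        yield key, grp["time_h"].to_numpy(dtype=float), \
            grp["cells"].to_numpy(dtype=float)


def write_bundle(bundle, outdir: str) -> dict:
    """Write an :class:`~aletrack.simulate.ExperimentBundle` to a directory.

    Produces ``curves.csv``, ``layout.csv``, ``strains.csv`` and
    ``truth.csv``; returns the mapping of logical name to path.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, df in (("curves", bundle.curves), ("layout", bundle.layout),
                     ("strains", bundle.strains), ("truth", bundle.truth)):
        p = os.path.join(outdir, f"{name}.csv")
        write_table(df, p)
        paths[name] = p
    return paths
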