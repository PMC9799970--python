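"""Event-table and report I/O.

The canonical event table is a CSV with columns
``species, mg_mM, treatment, trap_force_pn, amplitude_nm`` (one row per
pulse).  Deposited spreadsheet source data can be imported into the same
schema; each sheet is expected to carry one condition with per-column force
levels or explicit force/amplitude columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["species", "mg_mM", "treatment", "trap_force_pn", "amplitude_nm"]


class EventTableError(ValueError):
    pass


def read_event_table(path) -> pd.DataFrame:
    """Read a per-event CSV, validating the canonical schema.

    Malformed rows are reported with their (1-based, header-inclusive) row
    numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("trap_force_pn", "amplitude_nm") if c not in df.columns]
    if missing:
        raise EventTableError(f"{path}: missing required columns {missing}")
    for col, default in (("species", ""), ("mg_mM", np.nan), ("treatment", "")):
        if col not in df.columns:
            df[col] = default
    bad_rows = []
    for col in ("trap_force_pn", "amplitude_nm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()] + 2  # header + 1-based
        bad_rows.extend((int(i), col) for i in bad)
        df[col] = vals
    if bad_rows:
        desc = ", ".join(f"row {i} ({col})" for i, col in bad_rows[:10])
        raise EventTableError(f"{path}: non-numeric values at {desc}")
    df = df.dropna(subset=["trap_force_pn", "amplitude_nm"])
    return df[EVENT_COLUMNS + [c for c in df.columns if c not in EVENT_COLUMNS]]


def write_event_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def import_spreadsheet(
    path,
    species: str = "",
    mg_mM: float = float("nan"),
    treatment: str = "",
    sheet_name=0,
) -> pd.DataFrame:
    """Import one sheet of a deposited source-data spreadsheet.

    Two layouts are recognised: explicit ``trap_force_pn`` /
    ``amplitude_nm`` columns (after case/space normalisation), or a wide
    layout where each column is one trap-force level (numeric header, pN)
    and cells are individual pulse amplitudes (nm).
    """
    raw = pd.read_excel(path, sheet_name=sheet_name)
    norm = {c: str(c).strip().lower().replace(" ", "_") for c in raw.columns}
    df = raw.rename(columns=norm)

    force_col = next(
        (c for c in df.columns if "force" in c), None
    )
    amp_col = next((c for c in df.columns if "amplitude" in c or "amp" == c), None)
    if force_col and amp_col:
        long = pd.DataFrame(
            {
                "trap_force_pn": pd.to_numeric(df[force_col], errors="coerce"),
                "amplitude_nm": pd.to_numeric(df[amp_col], errors="coerce"),
            }
        ).dropna()
    else:
        # wide layout: numeric column headers are force levels
        cols = []
        for c in raw.columns:
            try:
                f = float(str(c).strip().rstrip("pN").strip())
            except ValueError:
                continue
            amps = pd.to_numeric(raw[c], errors="coerce").dropna()
            cols.append(
                pd.DataFrame({"trap_force_pn": f, "amplitude_nm": amps.to_numpy()})
            )
        if not cols:
            raise EventTableError(
                f"{path}: no force/amplitude columns recognised in sheet {sheet_name!r}"
            )
        long = pd.concat(cols, ignore_index=True)
    long.insert(0, "species", species)
    long.insert(1, "mg_mM", mg_mM)
    long.insert(2, "treatment", treatment)
    return long


def write_fit_report(report: dict, path) -> None:
    """Write a fit/work report as JSON (lists for arrays, units in keys)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
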