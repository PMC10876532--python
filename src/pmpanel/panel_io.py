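"""Panel CSV reading/writing with schema validation and inclusion filters."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .constants import CONSTITUENTS, COVARIATES, OUTCOMES

__all__ = ["PANEL_COLUMNS", "read_panel", "write_panel"]

log = logging.getLogger("pmpanel")

PANEL_COLUMNS = (
    ["zip_id", "year", "beneficiaries"]
    + [f"count_{o}" for o in OUTCOMES]
    + ["pm25"]
    + list(CONSTITUENTS)
    + list(COVARIATES)
)

_NUMERIC = [c for c in PANEL_COLUMNS if c != "zip_id"]


def read_panel(path, min_beneficiaries: int = 100) -> pd.DataFrame:
    """Read and validate a panel CSV.

    ZIP-code-years with ``beneficiaries <= min_beneficiaries`` are dropped
    (the cohort includes only ZIP codes with more than 100 beneficiaries);
    the dropped-row count is logged.  Missing columns, non-numeric cells,
    duplicate (zip_id, year) pairs and negative concentrations are errors.
    """
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel is missing columns: {missing}")
    for c in _NUMERIC:
        try:
            df[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
            row = int(df.index[bad][0]) if bad.any() else "?"
            raise ValueError(f"non-numeric value in column {c!r}, row {row}") from exc
    if df.duplicated(["zip_id", "year"]).any():
        raise ValueError("duplicate (zip_id, year) rows")
    conc = df[["pm25"] + list(CONSTITUENTS)].to_numpy(dtype=float)
    if (conc < 0).any():
        raise ValueError("negative concentrations in panel")
    count_cols = [f"count_{o}" for o in OUTCOMES]
    if (df[count_cols].to_numpy() < 0).any():
        raise ValueError("negative counts in panel")

    n0 = len(df)
    df = df[df["beneficiaries"] > min_beneficiaries].reset_index(drop=True)
    if len(df) < n0:
        log.info(
            "dropped %d zip-year rows with <= %d beneficiaries",
            n0 - len(df),
            min_beneficiaries,
        )
    if df.empty:
        raise ValueError("no rows left after beneficiary filter")
    return df


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write a panel CSV in canonical column order (deterministic bytes)."""
    extra = [c for c in panel.columns if c not in PANEL_COLUMNS]
    panel[PANEL_COLUMNS + extra].to_csv(path, index=False, float_format="%.10g")
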