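"""Reading and validating tidy viability tables.

The on-disk format is one CSV row per well:

``cell_line, drug_a, conc_a_uM, drug_b, conc_b_uM, time_h, replicate,
viability_pct``

Concentrations are µM.  Files produced by other tools may carry optional
``conc_a_unit`` / ``conc_b_unit`` columns with values ``uM`` or ``mM``;
mM values are converted (×1000) on read and the unit columns dropped, so
everything downstream is single-unit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "read_viability_table", "validate_viability_table"]

REQUIRED_COLUMNS = [
    "cell_line",
    "drug_a",
    "conc_a_uM",
    "drug_b",
    "conc_b_uM",
    "time_h",
    "replicate",
    "viability_pct",
]

_KEY = ["cell_line", "drug_a", "conc_a_uM", "drug_b", "conc_b_uM", "time_h", "replicate"]
_UNIT_FACTORS = {"uM": 1.0, "µM": 1.0, "um": 1.0, "mM": 1000.0, "mm": 1000.0}


def _convert_units(df: pd.DataFrame) -> pd.DataFrame:
    for side in ("a", "b"):
        unit_col = f"conc_{side}_unit"
        if unit_col in df.columns:
            units = df[unit_col].astype(str)
            unknown = set(units) - set(_UNIT_FACTORS)
            if unknown:
                raise ValueError(f"unknown concentration units in {unit_col}: {sorted(unknown)}")
            df[f"conc_{side}_uM"] = df[f"conc_{side}_uM"] * units.map(_UNIT_FACTORS)
            df = df.drop(columns=[unit_col])
    return df


def validate_viability_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema, units, signs and key uniqueness; return the typed table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = _convert_units(df.copy())
    for col in ("conc_a_uM", "conc_b_uM", "time_h", "viability_pct"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["replicate"] = df["replicate"].astype(int)

    bad = df.index[
        (df["conc_a_uM"] < 0)
        | (df["conc_b_uM"] < 0)
        | (df["time_h"] < 0)
        | (df["viability_pct"] < 0)
    ].tolist()
    if bad:
        raise ValueError(f"negative concentration/time/viability at rows {bad[:20]}")
    if not np.all(np.isfinite(df[["conc_a_uM", "conc_b_uM", "time_h", "viability_pct"]])):
        raise ValueError("non-finite numeric values present")

    dup = df.duplicated(subset=_KEY, keep=False)
    if dup.any():
        raise ValueError(
            f"duplicate (arm, time, replicate) keys at rows {df.index[dup].tolist()[:20]}"
        )
    return df[REQUIRED_COLUMNS]


def read_viability_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy viability CSV (see module docstring for schema)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return validate_viability_table(pd.read_csv(path))
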