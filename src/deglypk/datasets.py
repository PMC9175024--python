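"""Long-format concentration-time dataset reading, validation and writing.

One CSV dialect (RFC-4180, UTF-8, "." decimal) with columns::

    subject_id, group, route, analyte, dose_mg_per_kg, time_h,
    conc_nmol_per_L, blq [, conc_raw_nmol_per_L]

``blq`` marks below-LLOQ records; their ``conc_nmol_per_L`` cell may be
empty or the literal ``BLQ``.  The optional shadow column keeps the
pre-censoring simulated value for testing.  Floats are written with
``repr`` so a read/write round trip is byte-identical.
"""

from __future__ import annotations

import csv
import io
import math
from pathlib import Path

import pandas as pd

from .exceptions import IntegrityError, SchemaError
from .model import Analyte, Route
from .parameters import build_parameter_set

REQUIRED_COLUMNS = (
    "subject_id",
    "group",
    "route",
    "analyte",
    "dose_mg_per_kg",
    "time_h",
    "conc_nmol_per_L",
    "blq",
)
SHADOW_COLUMN = "conc_raw_nmol_per_L"

__all__ = ["read_dataset", "write_dataset", "validate_dataset", "read_parameters", "REQUIRED_COLUMNS"]


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and invariants; returns the frame (types coerced)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    df = df.copy()
    for col in ("dose_mg_per_kg", "time_h", "conc_nmol_per_L"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df["blq"].dtype != bool:
        df["blq"] = (
            df["blq"].astype(str).str.strip().str.lower().map({"true": True, "false": False})
        )
        if df["blq"].isna().any():
            raise SchemaError("blq column must contain only True/False")
    for value in df["route"].unique():
        Route(value)
    for value in df["analyte"].unique():
        Analyte(value)
    if (df["time_h"] < 0).any():
        raise IntegrityError("negative time_h")
    if df["dose_mg_per_kg"].isna().any() or (df["dose_mg_per_kg"] < 0).any():
        raise IntegrityError("dose_mg_per_kg must be non-negative")
    quant = ~df["blq"]
    if df.loc[quant, "conc_nmol_per_L"].isna().any():
        raise IntegrityError("non-BLQ record with missing concentration")
    if (df.loc[quant, "conc_nmol_per_L"] < 0).any():
        raise IntegrityError("negative concentration")
    dup = df.duplicated(subset=["subject_id", "analyte", "time_h"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["subject_id", "analyte", "time_h"]].tolist()
        raise IntegrityError(f"duplicate (subject_id, analyte, time_h) key: {key}")
    return df


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a dataset CSV, preserving row order."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh), None)
    if header is None:
        raise SchemaError(f"{path}: empty file")
    expected = list(REQUIRED_COLUMNS)
    if header not in (expected, expected + [SHADOW_COLUMN]):
        missing = [c for c in expected if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s): {missing}")
        raise SchemaError(f"{path}: header does not match dataset schema: {header}")
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str}, float_precision="round_trip")
    df["conc_nmol_per_L"] = pd.to_numeric(
        df["conc_nmol_per_L"].replace({"BLQ": None, "": None}), errors="coerce"
    )
    return validate_dataset(df)


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(value)
    return str(value)


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Write a validated dataset in the canonical dialect."""
    df = validate_dataset(df)
    cols = list(REQUIRED_COLUMNS) + ([SHADOW_COLUMN] if SHADOW_COLUMN in df.columns else [])
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(cols)
    for row in df[cols].itertuples(index=False):
        writer.writerow([_fmt(v) for v in row])
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_parameters(path: str | Path):
    """Read a flat YAML/JSON parameter file into a validated ParameterSet.

    Keys are ParameterSet field names (``k_e`` accepted); unknown keys are
    rejected by the builder.
    """
    import yaml

    with Path(path).open(encoding="utf-8") as fh:
        values = yaml.safe_load(fh)
    if not isinstance(values, dict):
        raise SchemaError(f"{path}: expected a mapping of parameter names to values")
    return build_parameter_set(values)
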