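"""Validated CSV readers/writers for the pipeline's table schemas.

One dialect only: comma-separated, "." decimals, ISO-8601 dates, header
required.  Validation errors cite file, 1-based data row, and column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "TableSchema",
    "ValidationError",
    "REARING_SCHEMA",
    "WEATHER_SCHEMA",
    "SURVEY_SCHEMA",
    "read_table",
    "write_table",
]


class ValidationError(ValueError):
    """A table failed schema or consistency checks."""


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: dict  # column -> dtype ("str", "float", "int", "date")
    optional: tuple = ()
    row_checks: tuple = ()  # (description, callable(row_series) -> bool ok)


def _rearing_checks():
    return (
        ("dev_days must be > 0", lambda r: r["dev_days"] > 0),
        ("mass_g must be > 0", lambda r: r["mass_g"] > 0),
        ("tvar_c must be >= 0", lambda r: r["tvar_c"] >= 0),
    )


def _weather_checks():
    return (("tmax_c must be >= tmin_c", lambda r: r["tmax_c"] >= r["tmin_c"]),)


def _survey_checks():
    cols = [f"stage{i}" for i in range(1, 7)]
    return tuple(
        (f"{c} must be a non-negative integer", lambda r, c=c: r[c] >= 0) for c in cols
    )


REARING_SCHEMA = TableSchema(
    "rearing",
    {
        "site": "str",
        "elevation_m": "float",
        "sex": "str",
        "photoperiod": "str",
        "tvar_c": "float",
        "dev_days": "float",
        "mass_g": "float",
        "mother_id": "str",
    },
    optional=("elevation_m", "mother_id"),
    row_checks=_rearing_checks(),
)

WEATHER_SCHEMA = TableSchema(
    "weather",
    {"site": "str", "date": "date", "tmin_c": "float", "tmax_c": "float"},
    row_checks=_weather_checks(),
)

SURVEY_SCHEMA = TableSchema(
    "survey",
    {
        "site": "str",
        "date": "date",
        **{f"stage{i}": "int" for i in range(1, 7)},
    },
    row_checks=_survey_checks(),
)

GDD_SCHEMA = TableSchema(
    "gdd",
    {"site": "str", "date": "date", "doy": "int", "dd": "float", "gdd": "float"},
)

FITS_SCHEMA = TableSchema(
    "fits",
    {
        "model": "str",
        "site": "str",
        "photoperiod": "str",
        "sex": "str",
        "q10": "float",
        "c": "float",
        "residual_sd": "float",
        "n_obs": "int",
        "converged": "str",
    },
)

TIMING_SCHEMA = TableSchema(
    "timing",
    {
        "site": "str",
        "year": "int",
        "threshold": "float",
        "doy_at_threshold": "float",
        "gdd_at_threshold": "float",
        "status": "str",
    },
    optional=("doy_at_threshold", "gdd_at_threshold"),
)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV against a schema.

    Raises
    ------
    ValidationError
        Missing file/column, a non-parsable cell, or a row-level
        consistency failure — the message cites file, row (1-based data
        row), and column.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [
        c for c in schema.columns if c not in df.columns and c not in schema.optional
    ]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing} for {schema.name} table")
    out = pd.DataFrame(index=df.index)
    for col, kind in schema.columns.items():
        if col not in df.columns:
            continue
        raw = df[col]
        if kind == "str":
            out[col] = raw
            continue
        if kind == "date":
            parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        else:
            parsed = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = parsed.isna() & (raw != "")
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValidationError(
                f"{path}: row {row}, column {col!r}: "
                f"cannot parse {raw[bad.idxmax()]!r} as {kind}"
            )
        if kind == "int":
            nonint = parsed.dropna() % 1 != 0
            if nonint.any():
                row = int(nonint.idxmax()) + 1
                raise ValidationError(
                    f"{path}: row {row}, column {col!r}: not an integer"
                )
            parsed = parsed.astype("Int64")
        out[col] = parsed
    for desc, check in schema.row_checks:
        ok = out.apply(check, axis=1)
        if not ok.all():
            row = int((~ok).idxmax()) + 1
            raise ValidationError(f"{path}: row {row}: {desc}")
    return out.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a pipeline table as CSV (ISO dates, '.' decimals)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path
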