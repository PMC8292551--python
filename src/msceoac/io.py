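"""Typed CSV table reading/writing with schema validation.

All tables are comma-separated UTF-8 with a header row; sexes are encoded
"M"/"F" and birth cohorts by their decade start year (e.g. 1950).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError

__all__ = ["read_table", "write_table", "SCHEMAS", "validate_table"]


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: dict[str, str]  # column -> pandas dtype kind ('i','f','O','b')
    key: Optional[tuple[str, ...]]
    check: Optional[Callable[[pd.DataFrame], None]] = None


def _check_incidence(df: pd.DataFrame) -> None:
    bad = df[df["age_low"] >= df["age_high"]]
    if not bad.empty:
        raise SchemaError(
            f"incidence rows with age_low >= age_high at index {list(bad.index)}"
        )
    if (df["cases"] < 0).any():
        raise SchemaError("incidence 'cases' must be >= 0")
    if (df["person_years"] <= 0).any():
        raise SchemaError("incidence 'person_years' must be > 0")
    rate = df["cases"] / df["person_years"]
    if (rate >= 1.0).any():
        raise SchemaError("incidence implies rate >= 1 per person-year; check units")


def _check_census(df: pd.DataFrame) -> None:
    if (df["person_years"] < 0).any():
        raise SchemaError("census 'person_years' must be >= 0")
    if (df["age"] < 0).any():
        raise SchemaError("census 'age' must be >= 0")


def _check_gerd(df: pd.DataFrame) -> None:
    p = df["prevalence"]
    if ((p < 0) | (p > 1)).any():
        raise SchemaError("gerd 'prevalence' must lie in [0, 1]")


SCHEMAS: dict[str, TableSchema] = {
    "incidence": TableSchema(
        "incidence",
        {
            "sex": "O",
            "cohort": "i",
            "age_low": "f",
            "age_high": "f",
            "cases": "i",
            "person_years": "f",
        },
        key=("sex", "cohort", "age_low"),
        check=_check_incidence,
    ),
    "census": TableSchema(
        "census",
        {"year": "i", "sex": "O", "age": "i", "person_years": "f"},
        key=("year", "sex", "age"),
        check=_check_census,
    ),
    "gerd": TableSchema(
        "gerd",
        {"sex": "O", "age": "f", "prevalence": "f"},
        key=("sex", "age"),
        check=_check_gerd,
    ),
    "screening": TableSchema(
        "screening",
        {"age": "i", "sex": "O", "gerd": "b", "be_found": "b"},
        key=None,
    ),
}

_KIND_CAST = {"i": "int64", "f": "float64", "O": "object", "b": "bool"}


def validate_table(df: pd.DataFrame, schema_name: str, strict: bool = False) -> pd.DataFrame:
    """Validate and coerce a DataFrame against a named schema.

    Raises :class:`SchemaError` naming the offending column/rows; with
    ``strict`` unknown columns are rejected.
    """
    try:
        schema = SCHEMAS[schema_name]
    except KeyError:
        raise InputError(
            f"unknown schema {schema_name!r}; valid: {sorted(SCHEMAS)}"
        )
    if df.empty:
        raise InputError(f"{schema_name} table is empty")
    missing = set(schema.columns) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{schema_name} table missing column(s): {sorted(missing)}"
        )
    extra = set(df.columns) - set(schema.columns)
    if strict and extra:
        raise SchemaError(
            f"{schema_name} table has unknown column(s) in strict mode: {sorted(extra)}"
        )
    out = df.copy()
    for col, kind in schema.columns.items():
        try:
            out[col] = out[col].astype(_KIND_CAST[kind])
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{schema_name} column {col!r} has non-{_KIND_CAST[kind]} values: {exc}"
            )
        if kind in ("i", "f") and not np.all(np.isfinite(out[col].to_numpy(dtype=float))):
            raise SchemaError(f"{schema_name} column {col!r} has non-finite values")
    if schema.key is not None:
        dup = out.duplicated(subset=list(schema.key), keep=False)
        if dup.any():
            raise SchemaError(
                f"{schema_name} table has duplicate {schema.key} keys at rows "
                f"{list(out.index[dup])}"
            )
    if schema.check is not None:
        schema.check(out)
    return out


def read_table(path: str, schema_name: str, strict: bool = False) -> pd.DataFrame:
    """Read and validate a CSV table."""
    if not os.path.exists(path):
        raise InputError(f"table file not found: {path}")
    if os.path.getsize(path) == 0:
        raise InputError(f"table file is empty: {path}")
    df = pd.read_csv(path)
    return validate_table(df, schema_name, strict=strict)


def write_table(df: pd.DataFrame, path: str, schema_name: Optional[str] = None) -> None:
    """Write a CSV table, validating against a schema when given."""
    if schema_name is not None:
        df = validate_table(df, schema_name)
    df.to_csv(path, index=False)
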