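"""Tabular input validation against the module ingest schemas.

TSV is the canonical dialect (tab-separated, UTF-8, '.' decimal, header row
mandatory); CSV is accepted on ingest. ``validate_table`` returns the parsed
table together with an itemized, row-addressed error list rather than failing
on the first violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = ["SCHEMAS", "TableError", "ValidationResult", "validate_table"]


@dataclass(frozen=True)
class TableError:
    """One schema violation; row is the 1-based data row (0 = header level)."""

    row: int
    column: str
    message: str


@dataclass
class ValidationResult:
    table: pd.DataFrame | None
    errors: list[TableError] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_failed(self) -> pd.DataFrame:
        if self.errors:
            detail = "; ".join(
                f"row {e.row}, {e.column}: {e.message}" for e in self.errors[:10]
            )
            raise SchemaError(f"{len(self.errors)} validation error(s): {detail}")
        return self.table


def _positive(x) -> bool:
    return np.isfinite(x) and x > 0


def _non_negative(x) -> bool:
    return np.isfinite(x) and x >= 0


def _in_range(lo, hi) -> Callable:
    return lambda x: np.isfinite(x) and lo <= x <= hi


def _binary(x) -> bool:
    return x in (0, 1)


# schema: column -> (dtype kind, required, row validator or None, description)
SCHEMAS: dict[str, dict] = {
    "measurements": {
        "model_id": ("str", True, None, "model identifier"),
        "animal_id": ("str", True, None, "animal identifier"),
        "arm": ("str", True, None, "treatment arm label"),
        "day": ("int", True, _non_negative, "days since treatment start"),
        "length_mm": ("float", True, _positive, "caliper length > 0"),
        "width_mm": ("float", True, _positive, "caliper width > 0"),
    },
    "biomarker_panel": {
        "sample_id": ("str", True, None, "sample identifier"),
        "p16": ("float", False, _in_range(0, 4), "semiquantitative 0-4"),
        "prb": ("float", False, _in_range(0, 4), "semiquantitative 0-4"),
        "cyclin_e1": ("float", False, _in_range(0, 8), "Allred 0-8"),
        "cyclin_d1": ("float", False, _in_range(0, 8), "Allred 0-8"),
        "subtype": ("str", False, None, "intrinsic subtype label"),
        "ki67_pct": ("float", False, _in_range(0, 100), "percent KI67"),
    },
    "spheroid": {
        "model_id": ("str", True, None, "model identifier"),
        "condition": ("str", True, None, "treatment condition"),
        "replicate": ("int", True, _positive, "replicate index"),
        "area": ("float", True, _positive, "spheroid area > 0"),
    },
    "variants": {
        "sample_id": ("str", True, None, "sample identifier"),
        "gene": ("str", True, None, "gene symbol"),
        "protein_change": ("str", False, None, "HGVS-protein text"),
        "consequence": ("str", False, None, "controlled consequence term"),
    },
    "copy_number": {
        "sample_id": ("str", True, None, "sample identifier"),
        "gene": ("str", True, None, "gene symbol"),
        "log_ratio": ("float", False, np.isfinite, "CN log ratio"),
        "minor_cn": ("float", False, _non_negative, "minor allele CN"),
        "major_cn": ("float", False, _non_negative, "major allele CN"),
    },
    "cohort": {
        "patient_id": ("str", True, None, "patient identifier"),
        "exposed": ("int", True, _binary, "received the drug class (0/1)"),
        "mutation": ("int", True, _binary, "coding mutation flag (0/1)"),
        "deletion": ("int", True, _binary, "heterozygous deletion flag (0/1)"),
    },
}


def _read(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    path = Path(source)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def validate_table(source, schema: str) -> ValidationResult:
    """Validate a file path or DataFrame against a named ingest schema.

    Header, type and range checks are itemized per row (1-based, excluding the
    header). A missing required column short-circuits row checks for that
    column only.
    """
    if schema not in SCHEMAS:
        raise SchemaError(
            f"unknown schema {schema!r}; available: {sorted(SCHEMAS)}"
        )
    spec = SCHEMAS[schema]
    df = _read(source)
    errors: list[TableError] = []
    for col, (kind, required, check, desc) in spec.items():
        if col not in df.columns:
            if required:
                errors.append(
                    TableError(0, col, f"missing required column ({desc})")
                )
            continue
        series = df[col]
        if kind in ("int", "float"):
            coerced = pd.to_numeric(series, errors="coerce")
            bad_type = series.notna() & coerced.isna()
            for i in np.flatnonzero(bad_type.to_numpy()):
                errors.append(
                    TableError(int(i) + 1, col, f"not numeric: {series.iloc[i]!r}")
                )
            if required:
                for i in np.flatnonzero(series.isna().to_numpy()):
                    errors.append(TableError(int(i) + 1, col, "missing value"))
            df[col] = coerced
            if check is not None:
                vals = coerced.to_numpy(dtype=float)
                for i in range(len(vals)):
                    if np.isnan(vals[i]):
                        continue
                    if not check(vals[i]):
                        errors.append(
                            TableError(
                                int(i) + 1, col, f"out of range ({desc}): {vals[i]}"
                            )
                        )
        else:
            if required:
                blank = series.isna() | (series.astype(str).str.strip() == "")
                for i in np.flatnonzero(blank.to_numpy()):
                    errors.append(TableError(int(i) + 1, col, "missing value"))
    return ValidationResult(table=None if errors else df, errors=errors)
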