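"""Cohort and report CSV readers/writers.

One flat CSV dialect: comma separator, UTF-8, mandatory header, decimal
point (decimal commas are rejected with a clear message).  The cohort
header is documented in :data:`iolpower.cohort.COHORT_COLUMNS`.

An evaluation-only reader imports per-eye refraction tables (one column of
achieved clinical refractions and one back-calculated column per model,
plus an axial-length subgroup label) so outcome summaries can be recomputed
without any biometry or trained model; the column mapping is configurable
because deposited outcome tables name their columns differently.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_per_eye_errors_csv",
    "CohortFormatError",
]

_TEXT_COLUMNS = ("eye_id", "patient_id", "eye", "surgery_text", "finding_text", "diagnosis_text")
_NUMERIC_COLUMNS = tuple(c for c in COHORT_COLUMNS if c not in _TEXT_COLUMNS)


class CohortFormatError(ValueError):
    """The cohort CSV violates the documented format."""


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and type-check a cohort CSV.

    Missing numeric entries are kept as NaN (they trigger the downstream
    "incomplete" filter); malformed numerics raise a row-level error report.
    Missing mandatory columns are listed in one error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path.name}: missing mandatory columns: {missing}")
    out = df.copy()
    bad_rows: List[str] = []
    for col in _NUMERIC_COLUMNS:
        raw = df[col].str.strip()
        if raw.str.contains(",").any():
            rows = list((raw[raw.str.contains(",")]).index[:5] + 2)
            raise CohortFormatError(
                f"{path.name}: column {col!r} contains decimal commas "
                f"(e.g. CSV line {rows[0]}); use decimal points"
            )
        vals = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        malformed = vals.isna() & (raw != "")
        for idx in raw.index[malformed][:10]:
            bad_rows.append(f"line {idx + 2}: {col}={raw[idx]!r}")
        out[col] = vals
    if bad_rows:
        raise CohortFormatError(
            f"{path.name}: malformed numeric values:\n  " + "\n  ".join(bad_rows)
        )
    return out[COHORT_COLUMNS + [c for c in out.columns if c not in COHORT_COLUMNS]]


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort frame in the documented dialect."""
    cohort.to_csv(path, index=False, encoding="utf-8")


def read_per_eye_errors_csv(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    subgroup_column: Optional[str] = "SUBGROUP (AL)",
) -> pd.DataFrame:
    """Read a per-eye refraction/error table for evaluation-only mode.

    ``column_map`` maps source column names to method names, default
    ``{"CR": "CR", "SVM-RM": "SVM-RM", "ANN-EM": "MLNN-EM"}`` (the deposited
    outcome-table convention).  The optional subgroup column is normalized
    to upper case under ``subgroup``.  Returns a frame with ``eye_id``,
    method columns, and ``subgroup`` when available — directly consumable
    by :func:`iolpower.evaluation.pe_summary` per column.
    """
    if column_map is None:
        column_map = {"CR": "CR", "SVM-RM": "SVM-RM", "ANN-EM": "MLNN-EM"}
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in column_map if c not in df.columns]
    if missing:
        raise CohortFormatError(f"per-eye table missing columns: {missing}")
    out = pd.DataFrame()
    out["eye_id"] = (
        df["eye_id"] if "eye_id" in df.columns else [f"E{i:05d}" for i in range(len(df))]
    )
    for src, dst in column_map.items():
        out[dst] = pd.to_numeric(df[src], errors="raise")
    if subgroup_column and subgroup_column in df.columns:
        out["subgroup"] = df[subgroup_column].astype(str).str.strip().str.upper()
    return out
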