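"""Cohort CSV reading/writing.

The on-disk format is one row per patient with the
:class:`~appendiscore.presentation.PatientPresentation` field names as
header, booleans as 0/1, ``guarding_grade`` as none/light/medium/strong
and ``histopathology`` as the four-level enum or empty when unlabeled.
Validation failures are aggregated across rows so a bad file is reported
in one pass.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .errors import CohortValidationError
from .presentation import BOOL_FIELDS, FIELD_ORDER, PatientPresentation

__all__ = ["read_cohort", "write_cohort", "cohort_to_frame"]

_OPTIONAL_COLUMNS = {"nausea_or_vomiting", "histopathology"}
_REQUIRED_COLUMNS = [c for c in FIELD_ORDER if c not in _OPTIONAL_COLUMNS]


def _clean(value):
    if isinstance(value, np.generic):
        value = value.item()
    if isinstance(value, float) and np.isnan(value):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return value


def read_cohort(path: str | Path) -> list[PatientPresentation]:
    """Read and validate a cohort CSV.

    Unknown columns warn and are ignored; missing required columns, and
    any per-row validation failure, raise a single
    :class:`CohortValidationError` listing every offending row and field.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    unknown = [c for c in df.columns if c not in FIELD_ORDER]
    if unknown:
        warnings.warn(f"ignoring unknown column(s): {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError([(0, f"missing required column(s): {missing}")])

    cohort, failures = [], []
    for i, rec in enumerate(df.to_dict(orient="records")):
        rec = {k: _clean(v) for k, v in rec.items()}
        rec = {k: v for k, v in rec.items() if v is not None}
        try:
            cohort.append(PatientPresentation.model_validate(rec))
        except ValidationError as exc:
            for err in exc.errors():
                loc = ".".join(str(x) for x in err["loc"]) or "record"
                failures.append((i, f"{loc}: {err['msg']}"))
    if failures:
        raise CohortValidationError(failures)
    if not cohort:
        raise CohortValidationError([(0, "empty cohort file")])
    return cohort


def cohort_to_frame(cohort: Sequence[PatientPresentation]) -> pd.DataFrame:
    """Cohort as a DataFrame with the documented column set (enums as
    strings); the inverse of :func:`read_cohort` up to dtypes."""
    rows = []
    for p in cohort:
        d = p.model_dump()
        d["guarding_grade"] = p.guarding_grade.value
        d["histopathology"] = None if p.histopathology is None else p.histopathology.value
        rows.append(d)
    return pd.DataFrame(rows, columns=list(FIELD_ORDER))


def write_cohort(cohort: Sequence[PatientPresentation] | pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV (booleans as 0/1, empty histopathology cell for
    unlabeled patients)."""
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    df = df.copy()
    for c in BOOL_FIELDS:
        if c in df.columns:
            df[c] = df[c].astype("boolean").astype("Int64")
    df.to_csv(path, index=False)
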