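"""Cohort CSV I/O.

The cohort file format is a UTF-8 CSV with two header lines: the column
names, then a units row.  Decimal separator is '.', empty cell = missing.
The reader rejects a file whose units row disagrees with the expected
units for the known columns — unit mix-ups (protein g/L vs g/dL) silently
corrupt every derived acid-base quantity, so they are a hard error.
"""

from __future__ import annotations

import csv
import json

import pandas as pd

from .errors import ValidationError

__all__ = ["COLUMN_UNITS", "write_cohort", "read_cohort", "write_sidecar"]

COLUMN_UNITS = {
    "id": "",
    "age": "days",
    "ph": "pH",
    "pco2": "mm Hg",
    "po2": "mm Hg",
    "rectal_temp": "degC",
    "heart_rate": "beats/min",
    "resp_rate": "breaths/min",
    "na": "mmol/L",
    "k": "mmol/L",
    "cl": "mmol/L",
    "d_lactate": "mmol/L",
    "l_lactate": "mmol/L",
    "glucose": "mmol/L",
    "total_protein": "g/L",
    "albumin": "g/L",
    "phosphorus": "mmol/L",
    "urea": "mmol/L",
    "creatinine": "umol/L",
    "ck": "U/L",
    "ast": "U/L",
    "ggt": "U/L",
    "gldh": "U/L",
    "hemoglobin": "g/dL",
    "pcv": "%",
    "mcv": "fL",
    "leukocytes": "G/L",
    "thrombocytes": "G/L",
    "hco3": "mmol/L",
    "base_excess": "mmol/L",
    "anion_gap": "mEq/L",
    "atot": "mmol/L",
    "a_minus": "mEq/L",
    "sid_m": "mEq/L",
    "sig": "mEq/L",
    "usi": "mEq/L",
    # scores/flags are dimensionless
}


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV with the units header row."""
    units = [COLUMN_UNITS.get(c, "") for c in df.columns]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(df.columns)
        w.writerow(units)
    df.to_csv(path, mode="a", header=False, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the units row for known columns."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
            units = next(reader)
        except StopIteration:
            raise ValidationError("file", f"{path}: not a cohort CSV (needs header + units rows)")
    for col, unit in zip(header, units):
        expected = COLUMN_UNITS.get(col)
        if expected is not None and unit != expected:
            raise ValidationError(
                col, f"{path}: unit {unit!r} disagrees with expected {expected!r}"
            )
    return pd.read_csv(path, skiprows=[1])


def write_sidecar(spec_dict: dict, path) -> None:
    """Record the generating spec + seed next to a simulated cohort."""
    with open(path, "w") as fh:
        json.dump(spec_dict, fh, indent=2, default=str)
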