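"""Delimited-text I/O for patient tables (comma-separated, header row,
UTF-8; missing endpoint scores as empty fields)."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DataError

REQUIRED_COLUMNS = (
    "patient_id",
    "arm",
    "baseline_phq9",
    "baseline_gad7",
)

NUMERIC_COLUMNS = (
    "patient_id",
    "clinician_id",
    "age",
    "unemployed",
    "baseline_phq9",
    "baseline_gad7",
    "wsas",
    "sapas",
    "latent_prognosis",
    "stepped_up",
    "sessions_lit",
    "sessions_hit",
    "sessions",
    "dropout",
    "post_phq9",
    "post_gad7",
    "latent_rcsi_phq9",
    "latent_rcsi_gad7",
    "adherent",
    "fast_track",
    "predicted_remission_prob",
    "caseness_phq9",
    "caseness_gad7",
    "rcsi_phq9",
    "rcsi_gad7",
    "reliable_improvement",
    "reliable_deterioration",
    "reliable_recovery",
    "cost",
)

KNOWN_COLUMNS = set(NUMERIC_COLUMNS) | {
    "arm",
    "sex",
    "ethnicity_group",
    "diagnosis",
    "complexity_label",
    "initial_intensity",
    "allocated_intensity",
    "recommended",
    "actual",
    "reason",
}


def write_patient_table(df: pd.DataFrame, path) -> None:
    """Write a patient table; missing endpoint fields become empty cells."""
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def read_patient_table(path) -> pd.DataFrame:
    """Read a patient table, validating required columns and numeric cells.

    Unknown columns warn; a malformed numeric cell raises with its line
    number (header = line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in KNOWN_COLUMNS]
    if unknown:
        warnings.warn(f"unknown columns in {path}: {unknown}", stacklevel=2)
    for col in df.columns:
        if col not in NUMERIC_COLUMNS:
            continue
        raw = df[col].replace("", np.nan)
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise DataError(
                f"malformed numeric cell in column {col!r} at line {line}: "
                f"{raw[bad.idxmax()]!r}"
            )
        df[col] = converted
    return df
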