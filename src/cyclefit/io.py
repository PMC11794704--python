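"""Readers and writers for the package's tabular and model artifacts.

CSV is the canonical tabular format (per-cell features, phase-count
series, screen summaries); model objects (transition matrices, fit
results) serialize to JSON including the config and seed that produced
them.  Times are stored in hours as reals.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .calling import FEATURE_COLUMNS
from .model import FitResult
from .series import PhaseCountSeries


class SchemaError(ValueError):
    """Raised when a table is missing required columns or has bad rows."""


def read_cell_features(path) -> pd.DataFrame:
    """Read a per-cell feature CSV and validate its schema.

    Required columns: cell_id, time_h, nucleus_count and the four
    intensity summaries.  Malformed rows are reported by line number
    (header is line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    numeric = [c for c in FEATURE_COLUMNS if c != "cell_id"]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any() or parsed.isna().any():
            row = int(df.index[parsed.isna()][0])
            raise SchemaError(
                f"{path}: malformed value in column '{col}' at data row {row + 1} "
                f"(file line {row + 2})"
            )
        df[col] = parsed
    bad_nuc = (df["nucleus_count"] < 1) | (df["nucleus_count"] % 1 != 0)
    if bad_nuc.any():
        row = int(df.index[bad_nuc][0])
        raise SchemaError(
            f"{path}: nucleus_count must be a positive integer at data row {row + 1}"
        )
    df["nucleus_count"] = df["nucleus_count"].astype(int)
    return df


def write_cell_features(df: pd.DataFrame, path) -> None:
    cols = [c for c in FEATURE_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in FEATURE_COLUMNS
    ]
    df.loc[:, cols].to_csv(path, index=False)


def read_phase_counts(path, sort: bool = False) -> PhaseCountSeries:
    """Read a phase-count series CSV (columns time_h, G1, S/G2, M,
    Multinucleated); non-monotone time is an error unless ``sort=True``."""
    return PhaseCountSeries.from_csv(path, sort=sort)


def write_phase_counts(series: PhaseCountSeries, path) -> None:
    series.to_csv(path)


def write_fit_result(result: FitResult, path) -> None:
    """Serialize a fit result (matrices, errors, config, seed) as JSON."""
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def read_fit_result(path) -> FitResult:
    with open(path) as fh:
        return FitResult.from_dict(json.load(fh))


def read_well_summaries(path) -> pd.DataFrame:
    """Read a screen well-summary CSV.

    Required columns: cell_line, treatment, sirna, replicate, cell_count,
    multinucleated_count.  Gate-tally columns are optional but validated
    against cell_count when present.
    """
    df = pd.read_csv(path)
    required = [
        "cell_line", "treatment", "sirna", "replicate",
        "cell_count", "multinucleated_count",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if (df["multinucleated_count"] > df["cell_count"]).any():
        raise SchemaError(f"{path}: multinucleated_count exceeds cell_count")
    tally_cols = [c for c in df.columns if c.startswith("n_")]
    for col in tally_cols:
        if (df[col] > df["cell_count"]).any():
            raise SchemaError(f"{path}: gate tally '{col}' exceeds cell_count")
    return df


def counts_to_json_safe(obj):
    """Recursively convert numpy scalars/arrays for json.dump."""
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: counts_to_json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [counts_to_json_safe(v) for v in obj]
    return obj
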