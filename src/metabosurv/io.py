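"""CSV/TSV dialects for cohort tables, spectral matrices and configs.

Cohort tables are plain UTF-8 CSV with '.' decimals, a fixed snake_case
header, and no missing values; spectral matrices are TSV with a patient_id
first column and bin centers printed to 3 decimals as the remaining headers.
Numeric fields round-trip at full precision (repr round-trip).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .nmr import SpectralMatrix

__all__ = [
    "COHORT_COLUMNS",
    "float_repr",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_spectra_tsv",
    "write_spectra_tsv",
    "load_yaml_config",
]

COHORT_COLUMNS = [
    "id",
    "age_years",
    "male",
    "hbv",
    "hcv",
    "ast",
    "alt",
    "ast_alt_ratio",
    "platelet",
    "fib4",
    "phe_um",
    "gln_um",
    "time_years",
    "event",
]

_INT_COLUMNS = {"male", "hbv", "hcv", "event"}


def float_repr(value) -> str:
    """Shortest round-tripping decimal representation of a float, for
    lossless CSV/TSV serialization."""
    return repr(float(value))


class ParseError(ValueError):
    """A file violated the documented dialect; the message names the
    offending column or row (header = line 1)."""


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"cohort table missing columns: {missing}")
    table[COHORT_COLUMNS].to_csv(path, index=False, float_format=float_repr)


def read_cohort_csv(path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    out = pd.DataFrame({"id": raw["id"].astype(str)})
    for col in COHORT_COLUMNS[1:]:
        try:
            # numpy strtod is correctly rounded, so repr-written values
            # round-trip exactly
            values = raw[col].to_numpy(dtype=float)
        except (ValueError, TypeError):
            probe = pd.to_numeric(raw[col], errors="coerce")
            bad = probe.isna() | raw[col].isna()
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +header +1-based
            raise ParseError(
                f"{path}: non-numeric or missing value in column {col!r} at line {line}"
            ) from None
        if np.any(np.isnan(values)):
            line = int(np.flatnonzero(np.isnan(values))[0]) + 2
            raise ParseError(f"{path}: missing value in column {col!r} at line {line}")
        out[col] = values.astype(int) if col in _INT_COLUMNS else values
    dup = out["id"].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ParseError(f"{path}: duplicate patient id {out['id'][dup].iloc[0]!r} at line {line}")
    return out


def write_spectra_tsv(matrix: SpectralMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format=float_repr)


def read_spectra_tsv(path) -> SpectralMatrix:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if frame.columns[0] != "patient_id":
        raise ParseError(f"{path}: first column must be 'patient_id'")
    try:
        centers = np.array([float(c) for c in frame.columns[1:]])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric bin header: {exc}") from exc
    values = frame.iloc[:, 1:].to_numpy()
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric intensity: {exc}") from exc
    return SpectralMatrix(frame["patient_id"].astype(str).tolist(), centers, values)


def load_yaml_config(path) -> dict:
    """Read a nested key/value config file; returns {} for an empty file."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: top level of config must be a mapping")
    return data
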