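"""CSV reading/writing with schema-by-name validation.

All tables are comma-separated UTF-8 with ``.`` decimals.  Columns are
matched by name, so reordered headers parse identically; unknown columns are
preserved.  Missing required columns and malformed rows are fatal, with the
offending column / line numbers in the message.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["SchemaError", "read_table", "read_peaks", "read_manifest", "write_table"]

PEAKS_REQUIRED = {"sample_id": str, "analyte": str, "role": str, "area": float}
MANIFEST_REQUIRED = {"sample_id": str, "sample_type": str, "dilution_label": str,
                     "nominal_ng_ml": float}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def read_table(path: str | Path, required: dict[str, type]) -> pd.DataFrame:
    """Read a CSV and validate required columns and their parseability.

    Raises :class:`SchemaError` naming any missing column, or any row (1-based
    line number, header = line 1) whose value cannot be coerced.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    for col, typ in required.items():
        if typ is float:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                lines = [int(i) + 2 for i in bad[:5]]
                raise SchemaError(
                    f"{path}: column {col!r} has non-numeric values at line(s) {lines}"
                )
            df[col] = coerced
    return df


def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read a long-format peak-area table (sample_id, analyte, role, area)."""
    df = read_table(path, PEAKS_REQUIRED)
    bad_role = ~df["role"].isin(["quantifier", "qualifier"])
    if bad_role.any():
        lines = [int(i) + 2 for i in df.index[bad_role][:5]]
        raise SchemaError(f"{path}: unknown transition role at line(s) {lines}")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest; extra columns are kept as-is."""
    return read_table(path, MANIFEST_REQUIRED)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as locale-independent CSV (UTF-8, '.' decimal)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
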