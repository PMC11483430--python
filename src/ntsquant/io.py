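"""CSV input/output for peak tables, compound metadata and results.

All files are RFC-4180 CSV, UTF-8, dot decimal separator.  Concentrations
are stored in mol/L; a mass-concentration column (``known_conc_ug_l``) is
accepted on input when the compound table supplies molecular weights.
"""

from __future__ import annotations

import os

import pandas as pd

from .datamodel import (
    ACCURACY_COLUMNS,
    COMPOUND_COLUMNS,
    PEAK_COLUMNS,
    QUANT_COLUMNS,
    SchemaError,
    ValidationError,
    ug_per_l_to_mol_per_l,
    validate_compounds,
    validate_peaks,
)

__all__ = [
    "read_peak_table",
    "write_peak_table",
    "read_compounds",
    "write_compounds",
    "read_results",
    "write_results",
    "read_accuracy",
    "write_accuracy",
]

_PEAK_DTYPES = {
    "dataset_id": str,
    "sample_id": str,
    "matrix": str,
    "level": str,
    "compound_id": str,
}


def read_peak_table(path, compounds: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a long-format peak table.

    Each row is one integrated peak in one sample/replicate of one dataset.
    If the file carries ``known_conc_ug_l`` instead of molar ``known_conc``,
    a ``compounds`` table with ``mw`` (g/mol) must be supplied for the
    conversion.
    """
    df = pd.read_csv(path, dtype=_PEAK_DTYPES)
    if "known_conc" not in df.columns and "known_conc_ug_l" in df.columns:
        if compounds is None or "mw" not in compounds.columns:
            raise SchemaError(
                "peak table reports known_conc_ug_l; a compound table with "
                "mw is required to convert to mol/L"
            )
        mw = df["compound_id"].map(compounds.set_index("id")["mw"])
        if mw.isna().any() and df["known_conc_ug_l"].notna().any():
            missing = df.loc[
                mw.isna() & df["known_conc_ug_l"].notna(), "compound_id"
            ].unique()
            raise ValidationError(
                f"no molecular weight for compound(s): {sorted(missing)}"
            )
        df["known_conc"] = ug_per_l_to_mol_per_l(df["known_conc_ug_l"], mw.fillna(1.0))
        df.loc[df["known_conc_ug_l"].isna(), "known_conc"] = float("nan")
        df = df.drop(columns=["known_conc_ug_l"])
    return validate_peaks(df)


def write_peak_table(df: pd.DataFrame, path) -> None:
    validate_peaks(df)
    df.loc[:, PEAK_COLUMNS].to_csv(path, index=False)


def read_compounds(path) -> pd.DataFrame:
    """Read compound metadata (fingerprints as hex strings)."""
    df = pd.read_csv(
        path, dtype={"id": str, "role": str, "fingerprint": str, "parent_id": str}
    )
    return validate_compounds(df)


def write_compounds(df: pd.DataFrame, path) -> None:
    validate_compounds(df)
    cols = [c for c in COMPOUND_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, index=False)


def write_results(results: pd.DataFrame, path) -> None:
    """Write quantification results; refuses an empty collection."""
    if results is None or len(results) == 0:
        raise ValidationError("refusing to write an empty result collection")
    cols = [c for c in QUANT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results.loc[:, cols].to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "dataset_id": str,
            "sample_id": str,
            "compound_id": str,
            "approach": str,
        },
    )
    missing = [
        c for c in ("dataset_id", "sample_id", "compound_id", "approach")
        if c not in df.columns
    ]
    if missing:
        raise SchemaError(f"results table missing column(s): {', '.join(missing)}")
    if "surrogate_id" in df.columns:
        df["surrogate_id"] = df["surrogate_id"].astype("string").astype(object)
        df.loc[df["surrogate_id"].isna(), "surrogate_id"] = None
    return df


def write_accuracy(df: pd.DataFrame, path) -> None:
    if df is None or len(df) == 0:
        raise ValidationError("refusing to write an empty accuracy table")
    cols = [c for c in ACCURACY_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, index=False)


def read_accuracy(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={
            "dataset_id": str,
            "sample_id": str,
            "compound_id": str,
            "approach": str,
        },
    )


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
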