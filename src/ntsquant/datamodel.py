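"""Shared data model for non-target LC/ESI/HRMS quantification studies.

The pipeline operates on long (tidy) peak tables: one integrated peak per
row, identified by (dataset, sample, replicate, compound).  Concentrations
are carried internally in mol/L and retention times in minutes.  Scalar
results of the individual stages (calibration fits, ionization-efficiency
harmonizations, surrogate assignments) are small frozen dataclasses; bulk
data lives in pandas DataFrames with the column schemas declared here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "MATRICES",
    "CALIBRATION_LEVELS",
    "SUSPECT_LEVELS",
    "LEVELS",
    "APPROACHES",
    "PEAK_COLUMNS",
    "COMPOUND_COLUMNS",
    "QUANT_COLUMNS",
    "ACCURACY_COLUMNS",
    "SchemaError",
    "ValidationError",
    "ConfigError",
    "Compound",
    "CalibrationFit",
    "DeadTimeSpec",
    "Harmonization",
    "SurrogateAssignment",
    "ug_per_l_to_mol_per_l",
    "mol_per_l_to_ug_per_l",
    "fingerprint_to_bits",
    "bits_to_fingerprint",
    "validate_peaks",
    "validate_compounds",
]

ROLES = ("calibrant", "suspect", "ilis")
MATRICES = ("hplc", "tap", "surface")

CALIBRATION_LEVELS = tuple(f"calibration_{i}" for i in range(1, 7))
SUSPECT_LEVELS = ("high", "low")
LEVELS = CALIBRATION_LEVELS + SUSPECT_LEVELS + ("blank",)

#: The five quantification approaches compared in the study.  Three use a
#: surrogate standard (the TP's parent, the most structurally similar
#: calibrant, or the closest-eluting calibrant); two transfer predicted log
#: ionization efficiencies to instrument-specific response factors.
APPROACHES = (
    "parent_tp",
    "structural_similarity",
    "close_eluting",
    "ie_predictor_A",
    "ie_predictor_B",
)

PEAK_COLUMNS = (
    "dataset_id",
    "sample_id",
    "matrix",
    "level",
    "replicate",
    "compound_id",
    "rt",
    "area",
    "known_conc",
)

COMPOUND_COLUMNS = (
    "id",
    "role",
    "rt",
    "fingerprint",
    "parent_id",
    "mw",
    "log_ie_A",
    "log_ie_B",
)

QUANT_COLUMNS = (
    "dataset_id",
    "sample_id",
    "matrix",
    "level",
    "compound_id",
    "approach",
    "surrogate_id",
    "estimated_conc",
    "unquantifiable",
    "provenance",
)

ACCURACY_COLUMNS = (
    "dataset_id",
    "sample_id",
    "matrix",
    "level",
    "approach",
    "compound_id",
    "estimated_conc",
    "spiked_conc",
    "fold_error",
    "log_error",
)


class SchemaError(ValueError):
    """A table is missing mandatory columns or has malformed headers."""


class ValidationError(ValueError):
    """A row violates a data-model invariant (e.g. negative peak area)."""


class ConfigError(ValueError):
    """A study configuration violates its declared invariants."""


@dataclass(frozen=True)
class Compound:
    """One study compound: a calibrant, a suspect, or the isotope-labeled
    internal standard (ILIS) used for peak-area normalization.

    ``rt`` is the nominal retention time in minutes; each laboratory sees a
    stretched/shifted version of it.  ``log_ie`` values are predicted log
    ionization efficiencies, one per configured predictor.
    """

    id: str
    role: str
    rt: float
    fingerprint: str | None = None
    parent_id: str | None = None
    mw: float | None = None
    log_ie: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown compound role {self.role!r}")
        if not self.rt > 0:
            raise ValidationError(f"compound {self.id}: rt must be > 0")


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of normalized peak area against concentration for one
    calibrant in one dataset.  The slope is the response factor (RF):
    normalized area per mol/L."""

    compound_id: str
    slope: float
    intercept: float
    n_used: int
    r_squared: float
    usable: bool
    trimmed_levels: tuple[float, ...] = ()

    @property
    def positive_slope(self) -> bool:
        return np.isfinite(self.slope) and self.slope > 0


@dataclass(frozen=True)
class DeadTimeSpec:
    """Column geometry and flow used to estimate the hold-up (dead) time.

    Lengths in mm, flow in mL/min.  Porosity defaults to 0.65, a typical
    total porosity for packed reversed-phase columns.
    """

    column_length: float
    column_inner_diameter: float
    flow_rate: float
    porosity: float = 0.65

    def __post_init__(self) -> None:
        for name in ("column_length", "column_inner_diameter", "flow_rate"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"DeadTimeSpec.{name} must be > 0")
        if not 0 < self.porosity < 1:
            raise ValidationError("DeadTimeSpec.porosity must be in (0, 1)")


@dataclass(frozen=True)
class Harmonization:
    """Regression transferring predicted log IE to instrument-specific
    log10 RF using the co-analyzed calibrants."""

    slope: float
    intercept: float
    n_calibrants_used: int
    r_squared: float
    excluded_ids: tuple[str, ...] = ()

    @property
    def usable(self) -> bool:
        return self.n_calibrants_used >= 3 and np.isfinite(self.slope)

    def predicted_rf(self, log_ie: float) -> float:
        """Predicted response factor for a compound with the given log IE."""
        return float(10.0 ** (self.slope * log_ie + self.intercept))


@dataclass(frozen=True)
class SurrogateAssignment:
    """Choice of calibrant whose calibration curve quantifies a suspect.

    ``score`` is the Jaccard similarity for ``top1_similarity``, |dRT| in
    minutes for ``closest_rt``, and 1.0 for ``parent``.
    """

    suspect_id: str
    surrogate_id: str
    rule: str
    score: float

    def __post_init__(self) -> None:
        if self.rule not in ("parent", "top1_similarity", "closest_rt"):
            raise ValidationError(f"unknown assignment rule {self.rule!r}")


# ---------------------------------------------------------------------------
# units


def ug_per_l_to_mol_per_l(conc_ug_l, mw):
    """Convert a mass concentration (ug/L) to molar (mol/L) via the
    molecular weight in g/mol."""
    mw = np.asarray(mw, dtype=float)
    if np.any(mw <= 0):
        raise ValidationError("molecular weight must be > 0")
    return np.asarray(conc_ug_l, dtype=float) * 1e-6 / mw


def mol_per_l_to_ug_per_l(conc_mol_l, mw):
    """Inverse of :func:`ug_per_l_to_mol_per_l`."""
    mw = np.asarray(mw, dtype=float)
    if np.any(mw <= 0):
        raise ValidationError("molecular weight must be > 0")
    return np.asarray(conc_mol_l, dtype=float) * 1e6 * mw


# ---------------------------------------------------------------------------
# fingerprints

FP_NBITS = 256


def fingerprint_to_bits(hex_fp: str, n_bits: int = FP_NBITS) -> np.ndarray:
    """Decode a hex-encoded binary fingerprint into a 0/1 uint8 vector."""
    raw = bytes.fromhex(hex_fp)
    bits = np.unpackbits(np.frombuffer(raw, dtype=np.uint8))
    if bits.size != n_bits:
        raise ValidationError(
            f"fingerprint has {bits.size} bits, expected {n_bits}"
        )
    return bits


def bits_to_fingerprint(bits: np.ndarray) -> str:
    """Hex-encode a 0/1 bit vector (length divisible by 8)."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size % 8:
        raise ValidationError("fingerprint length must be a multiple of 8")
    return np.packbits(bits).tobytes().hex()


# ---------------------------------------------------------------------------
# table validation


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def validate_peaks(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format peak table against the data-model invariants.

    Returns the table unchanged; raises :class:`SchemaError` /
    :class:`ValidationError` on violation.
    """
    _require_columns(df, PEAK_COLUMNS, "peak table")
    if len(df) == 0:
        return df
    if (df["area"] < 0).any():
        bad = df.index[df["area"] < 0][0]
        raise ValidationError(f"negative peak area at row {bad}")
    if (df["rt"] < 0).any():
        raise ValidationError("negative retention time in peak table")
    bad_level = set(df["level"]) - set(LEVELS)
    if bad_level:
        raise ValidationError(f"unknown level value(s): {sorted(bad_level)}")
    bad_matrix = set(df["matrix"]) - set(MATRICES)
    if bad_matrix:
        raise ValidationError(f"unknown matrix value(s): {sorted(bad_matrix)}")
    key = ["dataset_id", "sample_id", "replicate", "compound_id"]
    if df.duplicated(key).any():
        raise ValidationError(
            "duplicate (dataset_id, sample_id, replicate, compound_id) rows"
        )
    is_cal = df["level"].isin(CALIBRATION_LEVELS)
    if df.loc[is_cal, "known_conc"].isna().any():
        raise ValidationError(
            "known_conc must be present for every calibration-level record"
        )
    return df


def validate_compounds(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a compound-metadata table."""
    _require_columns(df, ("id", "role", "rt"), "compound table")
    if df["id"].duplicated().any():
        raise ValidationError("compound ids must be unique within a study")
    bad_role = set(df["role"]) - set(ROLES)
    if bad_role:
        raise ValidationError(f"unknown role value(s): {sorted(bad_role)}")
    if "parent_id" in df.columns:
        parents = df.loc[df["parent_id"].notna(), "parent_id"]
        calibrants = set(df.loc[df["role"] == "calibrant", "id"])
        orphan = set(parents) - calibrants
        if orphan:
            raise ValidationError(
                f"parent_id refers to non-calibrant id(s): {sorted(orphan)}"
            )
    return df
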