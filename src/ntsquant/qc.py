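"""Data-quality pipeline for reprocessed peak tables.

Four stages, mirroring a harmonized reprocessing of heterogeneous
multi-laboratory data:

1. peak areas are normalized to the isotope-labeled internal standard
   (ILIS) detected in the same sample and replicate;
2. calibration curves (normalized area vs concentration) are fitted by OLS
   with automated endpoint trimming standing in for manual residual
   inspection — curves left with fewer than three in-range levels are
   unusable;
3. compounds eluting before the column dead time (estimated from column
   geometry and flow) are removed: they are unretained and their peaks
   unreliable;
4. suspect high/low peak-area ratios far from the designed dilution factor
   (below 5 or above 20 for a 10x dilution) flag non-linear measurements
   and are removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CalibrationFit, DeadTimeSpec, ValidationError
from .synthetic import ILIS_ID

__all__ = [
    "NormalizationError",
    "normalize_area",
    "normalize_peaks",
    "fit_calibration",
    "fit_all_calibrations",
    "estimate_dead_time",
    "dead_time_filter",
    "ratio_filter",
    "dataset_rt",
]


class NormalizationError(ValueError):
    """ILIS undetected or non-positive where normalization was requested."""


def normalize_area(area: float, ilis_area: float) -> float:
    """Normalized peak area: area of the analyte divided by the ILIS area
    measured in the same sample and replicate."""
    if not ilis_area > 0:
        raise NormalizationError("ILIS area must be > 0 for normalization")
    return area / ilis_area


def normalize_peaks(
    peaks: pd.DataFrame,
    ilis_id: str = ILIS_ID,
    fallback_raw: bool = False,
) -> pd.DataFrame:
    """Add a ``norm_area`` column: each peak divided by the ILIS peak of the
    same (dataset, sample, replicate).

    With ``fallback_raw=True`` the raw area is used wherever the ILIS was
    not detected (the "reported data" path, which worked on plain peak
    areas without accounting for ILIS signal variation); otherwise a
    missing or non-positive ILIS raises :class:`NormalizationError`.
    """
    key = ["dataset_id", "sample_id", "replicate"]
    ilis = peaks[peaks["compound_id"] == ilis_id]
    if (ilis["area"] <= 0).any():
        raise NormalizationError("non-positive ILIS area encountered")
    ilis_areas = ilis.set_index(key)["area"]
    if ilis_areas.index.duplicated().any():
        raise NormalizationError("multiple ILIS peaks in one sample/replicate")

    out = peaks[peaks["compound_id"] != ilis_id].copy()
    idx = pd.MultiIndex.from_frame(out[key])
    denom = ilis_areas.reindex(idx).values
    if fallback_raw:
        out["norm_area"] = np.where(np.isnan(denom), out["area"], out["area"] / denom)
    else:
        if np.isnan(denom).any():
            n = int(np.isnan(denom).sum())
            raise NormalizationError(
                f"ILIS undetected in {n} sample/replicate combination(s); "
                "pass fallback_raw=True to use raw areas"
            )
        out["norm_area"] = out["area"] / denom
    return out


# ---------------------------------------------------------------------------
# calibration


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, r^2 of an ordinary least-squares line."""
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def fit_calibration(
    levels,
    trim_threshold: float = 0.25,
    compound_id: str = "",
) -> CalibrationFit:
    """Fit a calibration line with iterative endpoint trimming.

    ``levels`` is a sequence of (concentration, replicate-averaged
    normalized area) pairs.  An OLS line is fitted and, while either
    endpoint (the lowest or highest remaining level) is out of the linear
    range, the worse endpoint is dropped and the line refitted.  Trimming
    only the endpoints reflects the physics of the linear range:
    saturation at the top, quantification limit at the bottom.  When fewer
    than three levels remain the curve is marked unusable.

    An endpoint is out of range when it deviates by more than
    ``trim_threshold`` (relative) from *both* the fitted line
    (|obs - pred| / |pred|) and proportional response (its area/conc ratio
    vs the geometric-mean ratio of the retained levels).  The double
    condition matters on log-spaced levels: the OLS intercept is estimated
    on the scale of the top-level areas, so its noise alone can dwarf the
    lowest-level signal, and judging low endpoints by the line-residual
    only would discard perfectly proportional data.  Genuine saturation or
    a detector floor violates both conditions and is trimmed.
    """
    pts = sorted((float(c), float(a)) for c, a in levels)
    trimmed: list[float] = []
    while True:
        if len(pts) < 3:
            slope, intercept, r2 = (np.nan, np.nan, np.nan)
            if len(pts) == 2:
                slope, intercept, r2 = _ols(
                    np.array([p[0] for p in pts]), np.array([p[1] for p in pts])
                )
            return CalibrationFit(
                compound_id=compound_id,
                slope=slope,
                intercept=intercept,
                n_used=len(pts),
                r_squared=r2,
                usable=False,
                trimmed_levels=tuple(trimmed),
            )
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        slope, intercept, r2 = _ols(x, y)
        pred = slope * x + intercept
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_line = np.abs(y - pred) / np.abs(pred)
            ratio = y / x
            gm = np.exp(np.mean(np.log(ratio))) if np.all(ratio > 0) else np.nan
            rel_prop = np.abs(ratio / gm - 1.0)
        rel_line[~np.isfinite(rel_line)] = np.inf
        rel_prop[~np.isfinite(rel_prop)] = np.inf
        rel = np.minimum(rel_line, rel_prop)
        lo_bad = rel[0] > trim_threshold
        hi_bad = rel[-1] > trim_threshold
        if not lo_bad and not hi_bad:
            usable = bool(np.isfinite(slope))
            return CalibrationFit(
                compound_id=compound_id,
                slope=slope,
                intercept=intercept,
                n_used=len(pts),
                r_squared=r2,
                usable=usable,
                trimmed_levels=tuple(trimmed),
            )
        drop = 0 if (lo_bad and (not hi_bad or rel[0] >= rel[-1])) else len(pts) - 1
        trimmed.append(pts[drop][0])
        del pts[drop]


def fit_all_calibrations(
    norm_peaks: pd.DataFrame, trim_threshold: float = 0.25
) -> dict[str, dict[str, CalibrationFit]]:
    """Fit calibration curves for every calibrant in every dataset.

    Uses calibration-level records (which carry ``known_conc``); replicate
    areas are arithmetic-mean averaged per level before fitting.  Returns
    ``{dataset_id: {compound_id: CalibrationFit}}``.
    """
    cal = norm_peaks[
        norm_peaks["level"].str.startswith("calibration")
        & norm_peaks["known_conc"].notna()
    ]
    fits: dict[str, dict[str, CalibrationFit]] = {}
    means = cal.groupby(["dataset_id", "compound_id", "known_conc"], sort=True)[
        "norm_area"
    ].mean()
    for (ds, cid), series in means.groupby(level=[0, 1], sort=True):
        series = series.droplevel([0, 1])
        fit = fit_calibration(
            zip(series.index.values, series.values),
            trim_threshold=trim_threshold,
            compound_id=cid,
        )
        fits.setdefault(ds, {})[cid] = fit
    return fits


# ---------------------------------------------------------------------------
# dead time


def estimate_dead_time(spec: DeadTimeSpec) -> float:
    """Column hold-up time in minutes: t0 = eps * pi * (d/2)^2 * L / F.

    Lengths in mm give a void volume in mm^3, converted to mL before
    dividing by the flow rate in mL/min.
    """
    volume_mm3 = (
        spec.porosity
        * np.pi
        * (spec.column_inner_diameter / 2.0) ** 2
        * spec.column_length
    )
    return float(volume_mm3 / 1000.0 / spec.flow_rate)


def dataset_rt(peaks: pd.DataFrame) -> pd.Series:
    """Observed retention time of each compound in each dataset (mean over
    its records), indexed by (dataset_id, compound_id).  The same compound
    elutes differently per laboratory, so RTs are always dataset-specific."""
    return peaks.groupby(["dataset_id", "compound_id"])["rt"].mean()


def dead_time_filter(
    peaks: pd.DataFrame, t0: float | dict[str, float]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove all records of compounds eluting before the dead time.

    ``t0`` is either one hold-up time (minutes) for all datasets or a
    ``{dataset_id: t0}`` mapping.  Removal is strict ("shorter than"): a
    compound at exactly t0 is retained.  Returns (kept records, removal
    log with one row per removed (dataset, compound)).
    """
    rts = dataset_rt(peaks)
    if isinstance(t0, dict):
        limits = rts.index.get_level_values(0).map(t0)
    else:
        if not t0 > 0:
            raise ValidationError("dead time must be > 0")
        limits = np.full(len(rts), float(t0))
    unretained = rts.index[rts.values < np.asarray(limits, dtype=float)]
    removed_keys = set(unretained)
    key = pd.MultiIndex.from_frame(peaks[["dataset_id", "compound_id"]])
    mask = key.isin(removed_keys)
    log = pd.DataFrame(
        [
            (ds, cid, rts.loc[(ds, cid)], "rt_before_dead_time")
            for ds, cid in sorted(removed_keys)
        ],
        columns=["dataset_id", "compound_id", "rt", "rule"],
    )
    return peaks[~mask].copy(), log


# ---------------------------------------------------------------------------
# dilution-ratio filter


def ratio_filter(
    peaks: pd.DataFrame,
    bounds: tuple[float, float] = (5.0, 20.0),
    area_column: str = "norm_area",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen suspect peaks by the high/low spike area ratio.

    For each (dataset, matrix, compound) detected at both suspect levels,
    the ratio of replicate-averaged areas (undiluted over diluted) is
    computed; the theoretical value is the dilution factor (10) for
    measurements in the linear range.  Records are removed iff the ratio
    falls strictly below ``bounds[0]`` or strictly above ``bounds[1]``
    (values at the bounds are kept).  Compounds detected at only one level
    are flagged, not ratio-filtered.

    Returns (kept records, report with one row per (dataset, matrix,
    compound) and its ratio/status).
    """
    lo, hi = bounds
    sus = peaks[peaks["level"].isin(("high", "low"))]
    means = (
        sus.groupby(["dataset_id", "matrix", "compound_id", "level"])[area_column]
        .mean()
        .unstack("level")
    )
    report_rows = []
    remove_keys = set()
    for key, row in means.iterrows():
        high = row.get("high", np.nan)
        low = row.get("low", np.nan)
        if np.isnan(high) or np.isnan(low):
            report_rows.append((*key, np.nan, "single_level"))
            continue
        if low == 0:
            report_rows.append((*key, np.nan, "undetected_at_low"))
            continue
        ratio = high / low
        if ratio < lo or ratio > hi:
            remove_keys.add(key)
            report_rows.append((*key, ratio, "removed_out_of_range"))
        else:
            report_rows.append((*key, ratio, "kept"))
    report = pd.DataFrame(
        report_rows, columns=["dataset_id", "matrix", "compound_id", "ratio", "status"]
    )

    is_sus_level = peaks["level"].isin(("high", "low"))
    key = pd.MultiIndex.from_frame(peaks[["dataset_id", "matrix", "compound_id"]])
    mask = key.isin(remove_keys) & is_sus_level
    return peaks[~mask].copy(), report
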