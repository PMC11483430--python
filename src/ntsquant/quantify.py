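"""The five standard-free quantification approaches.

Three surrogate-standard approaches use the calibration curve of a
co-analyzed calibrant to quantify a suspect:

* **parent_tp** — a transformation product is quantified with its parent
  compound's curve (pairing supplied as a table or via compound metadata);
* **structural_similarity** — the most structurally similar calibrant
  (top-1 Jaccard/Tanimoto similarity on binary fingerprints);
* **close_eluting** — the calibrant eluting closest in retention time,
  recomputed per dataset since RTs shift between laboratories.

Two ionization-efficiency approaches (predictors A and B) transfer
predicted log IE values to instrument-specific response factors through an
OLS "harmonization" regression of log10 RF on log IE over the usable
calibrants, then divide the normalized area by the predicted RF.  Only
protonated-species peak areas are consumed; the two predictors share one
code path and differ only in their supplied log IE values.

Approach unavailability (missing parent, missing fingerprint or log IE,
unusable surrogate curve) is a first-class result state, never silently
dropped: downstream statistics must detect incomplete datasets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    APPROACHES,
    CalibrationFit,
    Harmonization,
    SurrogateAssignment,
    ValidationError,
    fingerprint_to_bits,
)
from .qc import dataset_rt

__all__ = [
    "jaccard_similarity",
    "assign_parent",
    "assign_most_similar",
    "assign_close_eluting",
    "quantify_by_surrogate",
    "harmonize_ie",
    "quantify_by_ie",
    "run_all_approaches",
]

IE_APPROACHES = ("ie_predictor_A", "ie_predictor_B")


def jaccard_similarity(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Jaccard/Tanimoto similarity of two binary fingerprints."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _usable_calibrants(fits: dict[str, CalibrationFit]) -> list[str]:
    return [cid for cid, f in fits.items() if f.usable]


def assign_parent(
    suspect_id: str,
    pairing: dict[str, str],
    fits: dict[str, CalibrationFit],
) -> SurrogateAssignment | None:
    """Assign the listed parent calibrant to a TP suspect.

    Returns None (approach unavailable) when the suspect has no listed
    parent or the parent has no usable calibration in this dataset.
    Designated pairs are honored exactly as listed, including any
    deliberately swapped parent/TP entries.
    """
    parent = pairing.get(suspect_id)
    if parent is None:
        return None
    fit = fits.get(parent)
    if fit is None or not fit.usable:
        return None
    return SurrogateAssignment(
        suspect_id=suspect_id, surrogate_id=parent, rule="parent", score=1.0
    )


def assign_most_similar(
    suspect_id: str,
    compounds: pd.DataFrame,
    fits: dict[str, CalibrationFit],
    rts: pd.Series | None = None,
) -> SurrogateAssignment | None:
    """Top-1 structurally similar calibrant by Jaccard similarity.

    Ties are broken by smallest |dRT| (dataset RTs when supplied, nominal
    otherwise), then lexicographic id.  Unavailable when fingerprints are
    missing or no usable calibrant carries one.
    """
    meta = compounds.set_index("id")
    fp_raw = meta.at[suspect_id, "fingerprint"] if suspect_id in meta.index else None
    if fp_raw is None or (isinstance(fp_raw, float) and np.isnan(fp_raw)):
        return None
    fp_s = fingerprint_to_bits(fp_raw)
    sus_rt = _rt_of(suspect_id, meta, rts)

    best = None  # (-sim, |dRT|, id)
    for cid in sorted(_usable_calibrants(fits)):
        if cid not in meta.index:
            continue
        fp_c_raw = meta.at[cid, "fingerprint"]
        if fp_c_raw is None or (isinstance(fp_c_raw, float) and np.isnan(fp_c_raw)):
            continue
        sim = jaccard_similarity(fp_s, fingerprint_to_bits(fp_c_raw))
        drt = abs(_rt_of(cid, meta, rts) - sus_rt)
        key = (-sim, drt, cid)
        if best is None or key < best[0]:
            best = (key, cid, sim)
    if best is None:
        return None
    return SurrogateAssignment(
        suspect_id=suspect_id,
        surrogate_id=best[1],
        rule="top1_similarity",
        score=best[2],
    )


def _rt_of(cid: str, meta: pd.DataFrame, rts: pd.Series | None) -> float:
    if rts is not None and cid in rts.index:
        return float(rts.loc[cid])
    return float(meta.at[cid, "rt"])


def assign_close_eluting(
    suspect_id: str,
    fits: dict[str, CalibrationFit],
    rts: pd.Series,
) -> SurrogateAssignment | None:
    """Closest-eluting usable calibrant by dataset-specific retention time.

    Assignments are recomputed per dataset: the same suspect may get
    different surrogates in different laboratories.  Equidistant ties go to
    the earlier-eluting calibrant.
    """
    if suspect_id not in rts.index:
        return None
    sus_rt = float(rts.loc[suspect_id])
    best = None  # (|dRT|, rt, id)
    for cid in sorted(_usable_calibrants(fits)):
        if cid not in rts.index:
            continue
        rt = float(rts.loc[cid])
        key = (abs(rt - sus_rt), rt, cid)
        if best is None or key < best[0]:
            best = (key, cid)
    if best is None:
        return None
    return SurrogateAssignment(
        suspect_id=suspect_id,
        surrogate_id=best[1],
        rule="closest_rt",
        score=best[0][0],
    )


def quantify_by_surrogate(
    normalized_area: float,
    surrogate_fit: CalibrationFit,
    slope_only: bool = False,
) -> float | None:
    """Concentration from a surrogate's calibration line.

    Inverts the full line, conc = (area - intercept) / slope, or divides by
    the slope alone (``slope_only=True``, mimicking workflows that use the
    plain area/RF ratio).  Negative results are unquantifiable (None), as
    are non-positive slopes.
    """
    if not surrogate_fit.usable:
        raise ValidationError("surrogate calibration is not usable")
    if not surrogate_fit.positive_slope:
        return None
    if slope_only:
        conc = normalized_area / surrogate_fit.slope
    else:
        conc = (normalized_area - surrogate_fit.intercept) / surrogate_fit.slope
    return conc if conc >= 0 else None


def harmonize_ie(
    fits: dict[str, CalibrationFit],
    log_ie: pd.Series,
) -> Harmonization | None:
    """Fit the calibration-transfer regression log10(RF) ~ predicted log IE.

    Uses calibrants with a usable fit, a strictly positive response-factor
    slope, and an available log IE prediction.  Calibrants with
    non-positive slopes cannot enter a log regression; they are excluded
    and recorded in ``excluded_ids`` (negative slopes entering a
    harmonization is a known failure mode of unscreened data).  Returns
    None when fewer than three usable points remain.
    """
    excluded = tuple(
        sorted(
            cid
            for cid, f in fits.items()
            if f.usable and not f.positive_slope and cid in log_ie.index
        )
    )
    pts = [
        (float(log_ie.loc[cid]), np.log10(f.slope))
        for cid, f in sorted(fits.items())
        if f.usable
        and f.positive_slope
        and cid in log_ie.index
        and np.isfinite(log_ie.loc[cid])
    ]
    if len(pts) < 3:
        return None
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
    return Harmonization(
        slope=float(slope),
        intercept=float(intercept),
        n_calibrants_used=len(pts),
        r_squared=r2,
        excluded_ids=excluded,
    )


def quantify_by_ie(
    normalized_area: float,
    log_ie: float,
    harmonization: Harmonization,
) -> float | None:
    """Concentration from a predicted ionization efficiency.

    The harmonization maps log IE to a predicted response factor
    RF = 10^(slope*logIE + intercept); conc = area / RF.  Unavailable
    (None) when log IE is missing.
    """
    if log_ie is None or not np.isfinite(log_ie):
        return None
    if not harmonization.usable:
        raise ValidationError("harmonization is not usable")
    return float(normalized_area) / harmonization.predicted_rf(log_ie)


def run_all_approaches(
    peaks: pd.DataFrame,
    compounds: pd.DataFrame,
    fits: dict[str, dict[str, CalibrationFit]],
    pairing: dict[str, str] | None = None,
    slope_only: bool = False,
    approaches=APPROACHES,
) -> pd.DataFrame:
    """Quantify every detected suspect in every suspect-level sample with
    every available approach.

    ``peaks`` must carry ``norm_area``.  Replicates are averaged per
    (dataset, sample, compound) before quantification.  One row per
    (dataset x sample x suspect x approach); unavailable approaches yield a
    row with ``unquantifiable=True`` and the reason in ``provenance``.
    """
    if pairing is None:
        pairing = (
            compounds.dropna(subset=["parent_id"]).set_index("id")["parent_id"].to_dict()
            if "parent_id" in compounds.columns
            else {}
        )
    suspects = compounds.loc[compounds["role"] == "suspect", "id"].tolist()
    rts_all = dataset_rt(peaks)

    sus_peaks = peaks[
        peaks["level"].isin(("high", "low")) & peaks["compound_id"].isin(suspects)
    ]
    means = (
        sus_peaks.groupby(
            ["dataset_id", "sample_id", "matrix", "level", "compound_id"], sort=True
        )["norm_area"]
        .mean()
        .reset_index()
    )

    rows = []
    for ds, ds_means in means.groupby("dataset_id", sort=True):
        ds_fits = fits.get(ds, {})
        rts = rts_all.loc[ds] if ds in rts_all.index.get_level_values(0) else pd.Series(dtype=float)

        assignments: dict[tuple[str, str], SurrogateAssignment | None] = {}
        harmonizations: dict[str, Harmonization | None] = {}
        for sid in set(ds_means["compound_id"]):
            assignments[("parent_tp", sid)] = assign_parent(sid, pairing, ds_fits)
            assignments[("structural_similarity", sid)] = assign_most_similar(
                sid, compounds, ds_fits, rts
            )
            assignments[("close_eluting", sid)] = assign_close_eluting(
                sid, ds_fits, rts
            )
        for approach in IE_APPROACHES:
            if approach not in approaches:
                continue
            col = "log_ie_" + approach.rsplit("_", 1)[1]
            log_ie = compounds.set_index("id")[col].dropna()
            harmonizations[approach] = harmonize_ie(ds_fits, log_ie)

        meta = compounds.set_index("id")
        for _, rec in ds_means.iterrows():
            sid = rec["compound_id"]
            for approach in approaches:
                surrogate_id = None
                conc = None
                provenance = ""
                if approach in IE_APPROACHES:
                    harm = harmonizations.get(approach)
                    col = "log_ie_" + approach.rsplit("_", 1)[1]
                    log_ie = meta.at[sid, col] if col in meta.columns else np.nan
                    if harm is None:
                        provenance = "harmonization unavailable (<3 usable calibrants)"
                    elif not np.isfinite(log_ie):
                        provenance = "no predicted log IE for suspect"
                    else:
                        conc = quantify_by_ie(rec["norm_area"], float(log_ie), harm)
                        provenance = (
                            f"harmonized RF from {harm.n_calibrants_used} calibrants"
                        )
                else:
                    asg = assignments.get((approach, sid))
                    if asg is None:
                        provenance = "no surrogate available"
                    else:
                        surrogate_id = asg.surrogate_id
                        conc = quantify_by_surrogate(
                            rec["norm_area"], ds_fits[asg.surrogate_id], slope_only
                        )
                        provenance = f"{asg.rule}:{asg.surrogate_id} score={asg.score:.4g}"
                        if conc is None:
                            provenance += "; below calibration intercept"
                rows.append(
                    (
                        ds,
                        rec["sample_id"],
                        rec["matrix"],
                        rec["level"],
                        sid,
                        approach,
                        surrogate_id,
                        conc if conc is not None else np.nan,
                        conc is None,
                        provenance,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
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
        ],
    )
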