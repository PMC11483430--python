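"""Accuracy metrics, outlier statistics and approach comparisons.

Accuracy is assessed against the spiked (truth) concentrations with two
metrics: the symmetric **fold error** max(est/spiked, spiked/est) — a fold
error up to 10x is considered sufficiently accurate for risk assessment —
and the signed **log error** log10(est/spiked), whose sign separates over-
from underprediction.

Outliers are Tukey-whisker flags (outside 1.5x the interquartile range) on
per-(dataset, approach) groups of errors; flags within the 10x band are not
counted.  Each compound's outlier rate is 100 * occurrences /
opportunities, where an opportunity is one (metric x approach x sample x
dataset) cell in which the compound was detected and quantified.

Approaches are compared with the Friedman test on the per-sample matrix of
mean fold errors (datasets x approaches; incomplete datasets dropped since
the test needs equal group sizes), followed by Nemenyi all-pairs
comparisons when significant.  Matrix effects are tested by Wilcoxon
signed-rank on peak areas (not errors, to exclude the quantification
approach) pairing tap/surface against HPLC-grade water per level, with
Bonferroni adjustment over the comparison family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ValidationError

__all__ = [
    "fold_error",
    "log_error",
    "build_accuracy",
    "summarize_errors",
    "flag_outliers",
    "outlier_ledger",
    "nemenyi_friedman",
    "compare_approaches",
    "matrix_effect_test",
]


def fold_error(estimated, spiked):
    """Symmetric fold error max(est/spiked, spiked/est); always >= 1."""
    est = np.asarray(estimated, dtype=float)
    sp = np.asarray(spiked, dtype=float)
    if np.any(est <= 0) or np.any(sp <= 0):
        raise ValidationError("fold_error requires positive concentrations")
    return np.maximum(est / sp, sp / est)


def log_error(estimated, spiked):
    """Signed log10(est/spiked); negative means underprediction."""
    est = np.asarray(estimated, dtype=float)
    sp = np.asarray(spiked, dtype=float)
    if np.any(est <= 0) or np.any(sp <= 0):
        raise ValidationError("log_error requires positive concentrations")
    return np.log10(est / sp)


def build_accuracy(quant: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Join quantification results with the truth table and compute both
    error metrics.  Unquantifiable or non-positive estimates are dropped
    (they carry no error value); what remains is one row per quantified
    (dataset x sample x approach x compound) cell."""
    spiked = truth.set_index(["sample_id", "compound_id"])["conc"]
    out = quant.copy()
    idx = pd.MultiIndex.from_arrays([out["sample_id"], out["compound_id"]])
    out["spiked_conc"] = spiked.reindex(idx).values
    out = out[
        (~out["unquantifiable"].astype(bool))
        & (out["estimated_conc"] > 0)
        & (out["spiked_conc"] > 0)
    ].copy()
    out["fold_error"] = fold_error(out["estimated_conc"], out["spiked_conc"])
    out["log_error"] = log_error(out["estimated_conc"], out["spiked_conc"])
    return out.reset_index(drop=True)


def summarize_errors(rows: pd.DataFrame, group_keys=("approach",)) -> pd.DataFrame:
    """Mean, median and 95% quantile fold error plus the percentage of
    estimates within 10x error, per group.  The 95% quantile uses linear
    interpolation.  Empty groups are simply absent from the output."""
    if len(rows) == 0:
        raise ValidationError("summarize_errors requires a non-empty table")
    g = rows.groupby(list(group_keys))["fold_error"]
    out = g.agg(
        mean_fold_error="mean",
        median_fold_error="median",
        q95_fold_error=lambda s: float(np.quantile(s, 0.95)),
        n="size",
    )
    out["pct_within_10x"] = g.apply(lambda s: 100.0 * float((s <= 10).mean()))
    return out.reset_index()


def _tukey_fences(values: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def flag_outliers(
    accuracy: pd.DataFrame,
    group_keys=("dataset_id", "approach"),
    metrics=("fold_error", "log_error"),
    min_group: int = 4,
    within_band_fold: float = 10.0,
) -> pd.DataFrame:
    """Tukey-whisker outlier flags per group and metric.

    A value is flagged iff it lies outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] of
    its (dataset, approach) group.  Flags whose fold error is within the
    acceptability band (<= 10x) are dropped: they are accurate enough not
    to matter.  Groups smaller than ``min_group`` produce no flags.
    Returns the flagged accuracy rows with a ``metric`` column.
    """
    frames = []
    for metric in metrics:
        for _, grp in accuracy.groupby(list(group_keys), sort=True):
            if len(grp) < min_group:
                continue
            lo, hi = _tukey_fences(grp[metric].values)
            flagged = grp[(grp[metric] < lo) | (grp[metric] > hi)]
            flagged = flagged[flagged["fold_error"] > within_band_fold]
            if len(flagged):
                flagged = flagged.copy()
                flagged["metric"] = metric
                frames.append(flagged)
    if not frames:
        return accuracy.iloc[0:0].assign(metric=pd.Series(dtype=str))
    return pd.concat(frames, ignore_index=True)


def outlier_ledger(flags: pd.DataFrame, accuracy: pd.DataFrame) -> pd.DataFrame:
    """Per-compound outlier accounting.

    ``occurrences`` counts flagged (metric x approach x sample x dataset)
    cells; ``opportunities`` counts all such cells in which the compound
    was detected and quantified (its detection frequency across both error
    metrics); the outlier rate is 100 * occurrences / opportunities.
    ``n_datasets_flagged`` counts datasets where the compound was flagged
    at least once.
    """
    n_metrics = 2  # fold error and log error
    opp = (
        accuracy.groupby("compound_id")
        .size()
        .mul(n_metrics)
        .rename("opportunities")
    )
    if len(flags):
        occ = flags.groupby("compound_id").size().rename("occurrences")
        nds = (
            flags.groupby("compound_id")["dataset_id"]
            .nunique()
            .rename("n_datasets_flagged")
        )
    else:
        occ = pd.Series(dtype=int, name="occurrences")
        nds = pd.Series(dtype=int, name="n_datasets_flagged")
    ledger = (
        pd.concat([opp, occ, nds], axis=1)
        .fillna({"occurrences": 0, "n_datasets_flagged": 0})
        .reset_index()
        .rename(columns={"index": "compound_id"})
    )
    ledger = ledger[ledger["opportunities"] > 0]
    ledger["occurrences"] = ledger["occurrences"].astype(int)
    ledger["n_datasets_flagged"] = ledger["n_datasets_flagged"].astype(int)
    ledger["outlier_rate"] = 100.0 * ledger["occurrences"] / ledger["opportunities"]
    return ledger.sort_values(
        ["occurrences", "compound_id"], ascending=[False, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# statistical comparisons


def nemenyi_friedman(matrix: pd.DataFrame) -> pd.DataFrame:
    """Nemenyi all-pairs post hoc test after a Friedman test.

    ``matrix`` has blocks (datasets) as rows and treatments (approaches) as
    columns.  Pairwise statistic |R_i - R_j| / sqrt(k(k+1)/(6n)) referred
    to the studentized-range distribution (q / sqrt(2), k groups, infinite
    df).  Returns the symmetric p-value matrix.
    """
    ranks = matrix.rank(axis=1)
    mean_ranks = ranks.mean(axis=0)
    n, k = matrix.shape
    denom = np.sqrt(k * (k + 1) / (6.0 * n))
    cols = list(matrix.columns)
    p = pd.DataFrame(np.ones((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks.iloc[i] - mean_ranks.iloc[j]) / denom
            pv = float(stats.studentized_range.sf(q * np.sqrt(2.0), k, np.inf))
            p.iloc[i, j] = p.iloc[j, i] = min(1.0, pv)
    return p


def compare_approaches(
    accuracy: pd.DataFrame, alpha: float = 0.05
) -> dict[str, dict]:
    """Friedman test of mean fold errors across datasets and approaches,
    per sample, with Nemenyi all-pairs follow-up when significant.

    For each sample the datasets x approaches matrix of mean fold errors is
    assembled; datasets missing any approach are dropped first (the
    Friedman test requires equal group sizes) and recorded.  Fewer than
    three complete datasets skips the test with a reason.
    """
    report: dict[str, dict] = {}
    for sample_id, grp in accuracy.groupby("sample_id", sort=True):
        matrix = (
            grp.groupby(["dataset_id", "approach"])["fold_error"].mean().unstack()
        )
        complete = matrix.dropna()
        dropped = sorted(set(matrix.index) - set(complete.index))
        entry: dict = {"dropped_datasets": dropped, "n_datasets": len(complete)}
        if len(complete) < 3 or complete.shape[1] < 3:
            entry["skipped"] = (
                f"needs >= 3 complete datasets and >= 3 approaches, "
                f"have {complete.shape[0]} x {complete.shape[1]}"
            )
            report[sample_id] = entry
            continue
        row_tied = complete.nunique(axis=1) == 1
        if row_tied.all():
            # every block fully tied: no evidence of any difference
            statistic, pvalue = 0.0, 1.0
        else:
            statistic, pvalue = stats.friedmanchisquare(
                *[complete[c].values for c in complete.columns]
            )
        entry["friedman_statistic"] = float(statistic)
        entry["friedman_p"] = float(pvalue)
        if pvalue < alpha:
            entry["nemenyi_p"] = nemenyi_friedman(complete)
        report[sample_id] = entry
    return report


def matrix_effect_test(
    peaks: pd.DataFrame,
    alpha: float = 0.05,
    area_column: str = "area",
    min_pairs: int = 6,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Wilcoxon signed-rank tests for matrix effects on peak areas.

    For each matrix in {tap, surface} and each suspect level, replicate-
    averaged areas per (dataset, compound) are paired against the HPLC-
    grade-water sample of the same level (HPLC water is the matrix-free
    reference).  Bonferroni adjustment over the comparison family (all
    matrix x level combinations in the run, 4 by default).  Comparisons
    with fewer than ``min_pairs`` pairs are skipped with a reason.
    """
    sus = peaks[peaks["level"].isin(("high", "low"))]
    means = sus.groupby(
        ["dataset_id", "matrix", "level", "compound_id"], sort=True
    )[area_column].mean()

    rows = []
    for matrix in ("tap", "surface"):
        for level in ("high", "low"):
            try:
                ref = means.xs(("hplc", level), level=("matrix", "level"))
                alt = means.xs((matrix, level), level=("matrix", "level"))
            except KeyError:
                rows.append((matrix, level, 0, np.nan, np.nan, "no data"))
                continue
            paired = pd.concat([ref.rename("ref"), alt.rename("alt")], axis=1).dropna()
            n = len(paired)
            if n < min_pairs:
                rows.append(
                    (matrix, level, n, np.nan, np.nan, f"fewer than {min_pairs} pairs")
                )
                continue
            diff = paired["alt"] - paired["ref"]
            if np.allclose(diff, 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(paired["alt"], paired["ref"]).pvalue)
            rows.append((matrix, level, n, p, np.nan, ""))
    out = pd.DataFrame(
        rows, columns=["matrix", "level", "n_pairs", "p_value", "p_adjusted", "note"]
    )
    m = family_size if family_size is not None else int(out["p_value"].notna().sum())
    out["p_adjusted"] = np.minimum(1.0, out["p_value"] * max(m, 1))
    out["significant"] = out["p_adjusted"] < alpha
    return out
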