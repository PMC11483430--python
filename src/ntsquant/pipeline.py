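"""End-to-end orchestration: simulate -> qc -> quantify -> evaluate -> report.

One structured configuration drives all stages; every stage writes its
outputs as CSV/JSON into the run directory, and a run manifest records the
configuration hash, seed, package version and file digests so that a run
can be replayed and verified (identical manifest implies identical
outputs; figures are exempt from determinism).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import ConfigError
from .evaluate import (
    build_accuracy,
    compare_approaches,
    flag_outliers,
    matrix_effect_test,
    outlier_ledger,
    summarize_errors,
)
from .io import ensure_dir, write_accuracy, write_compounds, write_peak_table, write_results
from .qc import fit_all_calibrations, normalize_peaks, ratio_filter
from .quantify import run_all_approaches
from .synthetic import StudyConfig, SyntheticStudy, generate_study

__all__ = ["run_pipeline", "render_report", "config_from_dict", "run_manifest"]


def config_from_dict(raw: dict) -> StudyConfig:
    """Build a validated StudyConfig from a plain mapping (YAML/JSON)."""
    fields = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    kw = dict(raw)
    for name in ("cal_conc_range", "suspect_conc_range", "log10_rf_range", "rt_range"):
        if name in kw and isinstance(kw[name], (list, tuple)):
            kw[name] = tuple(float(v) for v in kw[name])
    cfg = StudyConfig(**kw)
    cfg.validate()
    return cfg


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_manifest(config: StudyConfig, outdir: str, files: list[str]) -> dict:
    cfg = dataclasses.asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {
        "config": cfg,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "version": __version__,
        "file_digests": {f: _digest(os.path.join(outdir, f)) for f in files},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def run_pipeline(
    config: StudyConfig,
    outdir: str,
    make_figures: bool = True,
) -> dict:
    """Run the full study: generate, QC, quantify, evaluate, report.

    Returns the report dict; writes all stage outputs into ``outdir``.
    """
    config.validate()
    ensure_dir(outdir)

    study = generate_study(config)
    write_compounds(study.compounds, os.path.join(outdir, "compounds.csv"))
    study.truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)
    study.samples.to_csv(os.path.join(outdir, "samples.csv"), index=False)
    for ds in study.lab_effects["dataset_id"]:
        write_peak_table(
            study.peaks_for(ds), os.path.join(outdir, f"peaks_{ds}.csv")
        )

    # QC: normalization, calibration fitting, ratio filter.  The dead-time
    # filter needs per-lab column geometry; the generator does not model
    # unretained compounds, so it is exercised separately (see qc module).
    norm = normalize_peaks(study.peaks)
    fits = fit_all_calibrations(norm)
    kept, ratio_report = ratio_filter(norm)
    ratio_report.to_csv(os.path.join(outdir, "qc_ratio_report.csv"), index=False)
    fit_rows = [
        {
            "dataset_id": ds,
            "compound_id": cid,
            "slope": f.slope,
            "intercept": f.intercept,
            "n_used": f.n_used,
            "r_squared": f.r_squared,
            "usable": f.usable,
            "trimmed_levels": ";".join(f"{t:g}" for t in f.trimmed_levels),
        }
        for ds, dsf in fits.items()
        for cid, f in dsf.items()
    ]
    pd.DataFrame(fit_rows).to_csv(
        os.path.join(outdir, "calibration_fits.csv"), index=False
    )

    quant = run_all_approaches(kept, study.compounds, fits)
    write_results(quant, os.path.join(outdir, "quant_results.csv"))

    accuracy = build_accuracy(quant, study.truth)
    write_accuracy(accuracy, os.path.join(outdir, "accuracy.csv"))
    summary = summarize_errors(accuracy, ("approach",))
    summary.to_csv(os.path.join(outdir, "summary.csv"), index=False)

    flags = flag_outliers(accuracy)
    ledger = outlier_ledger(flags, accuracy)
    ledger.to_csv(os.path.join(outdir, "outliers.csv"), index=False)

    friedman = compare_approaches(accuracy)
    wilcoxon = matrix_effect_test(study.peaks)
    wilcoxon.to_csv(os.path.join(outdir, "matrix_effects.csv"), index=False)

    report = render_report(
        accuracy,
        summary,
        ledger,
        friedman,
        wilcoxon,
        outdir=outdir if make_figures else None,
    )
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)

    files = sorted(
        f
        for f in os.listdir(outdir)
        if f.endswith((".csv", ".json")) and f != "manifest.json"
    )
    manifest = run_manifest(config, outdir, files)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report


def _jsonable_friedman(friedman: dict) -> dict:
    out = {}
    for sample, entry in friedman.items():
        e = dict(entry)
        if "nemenyi_p" in e and isinstance(e["nemenyi_p"], pd.DataFrame):
            e["nemenyi_p"] = {
                c: {r: float(e["nemenyi_p"].loc[r, c]) for r in e["nemenyi_p"].index}
                for c in e["nemenyi_p"].columns
            }
        out[sample] = e
    return out


def render_report(
    accuracy: pd.DataFrame,
    summary: pd.DataFrame,
    ledger: pd.DataFrame,
    friedman: dict,
    wilcoxon: pd.DataFrame,
    outdir: str | None = None,
) -> dict:
    """Assemble the study report (and box-plot figures when ``outdir`` is
    given): one summary row per approach, the outlier top list, and the
    statistical test tables."""
    report = {
        "n_accuracy_rows": int(len(accuracy)),
        "n_datasets": int(accuracy["dataset_id"].nunique()),
        "approaches": sorted(accuracy["approach"].unique()),
        "summary": summary.to_dict(orient="records"),
        "outliers": (
            ledger.head(20).to_dict(orient="records") if len(ledger) else "no outliers"
        ),
        "friedman": _jsonable_friedman(friedman),
        "matrix_effects": wilcoxon.to_dict(orient="records"),
    }
    if outdir is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        approaches = report["approaches"]
        fig, axes = plt.subplots(
            1, len(approaches), figsize=(3.2 * len(approaches), 4.2), sharey=True
        )
        axes = np.atleast_1d(axes)
        for ax, approach in zip(axes, approaches):
            sub = accuracy[accuracy["approach"] == approach]
            groups = [
                np.log10(g["fold_error"].values)
                for _, g in sub.groupby("dataset_id", sort=True)
            ]
            ax.boxplot(groups, showfliers=True)
            ax.axhline(1.0, color="green", lw=0.8, ls="--")  # 10x error band
            ax.set_title(approach, fontsize=9)
            ax.set_xlabel("dataset")
        axes[0].set_ylabel("log10 fold error")
        fig.tight_layout()
        fig.savefig(os.path.join(outdir, "fold_errors.svg"))
        plt.close(fig)
        report["figures"] = ["fold_errors.svg"]
    return report
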