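"""Accuracy evaluation and statistical comparison of the approaches.

Estimated concentrations are compared with the spiked truth via the
symmetric fold error (<= 10x is acceptable for risk assessment) and the
signed log error (negative = underprediction).  Tukey-whisker outliers are
tallied per compound, and approaches are compared with a Friedman test on
per-sample mean fold errors followed by Nemenyi all-pairs comparisons.
"""

from ntsquant import (
    StudyConfig,
    build_accuracy,
    compare_approaches,
    fit_all_calibrations,
    flag_outliers,
    generate_study,
    matrix_effect_test,
    normalize_peaks,
    outlier_ledger,
    ratio_filter,
    run_all_approaches,
    summarize_errors,
)

study = generate_study(StudyConfig(n_labs=6, seed=1))
norm = normalize_peaks(study.peaks)
fits = fit_all_calibrations(norm)
kept, _ = ratio_filter(norm)
quant = run_all_approaches(kept, study.compounds, fits)
accuracy = build_accuracy(quant, study.truth)

print("accuracy summary over all datasets and samples:")
summary = summarize_errors(accuracy, ("approach",))
for _, row in summary.iterrows():
    print(f"  {row['approach']:<22s} mean {row['mean_fold_error']:7.1f}x  "
          f"median {row['median_fold_error']:5.1f}x  "
          f"q95 {row['q95_fold_error']:7.1f}x  "
          f"within 10x {row['pct_within_10x']:5.1f}%")

flags = flag_outliers(accuracy)
ledger = outlier_ledger(flags, accuracy)
top = ledger.head(3)
print("\nmost frequent outlier compounds (occurrences / opportunities = rate):")
for _, row in top.iterrows():
    print(f"  {row['compound_id']}: {row['occurrences']} / "
          f"{row['opportunities']} = {row['outlier_rate']:.1f}%")

tests = compare_approaches(accuracy)
entry = tests["s1a"]
print(f"\nFriedman test (sample s1a, {entry['n_datasets']} datasets): "
      f"chi2 = {entry['friedman_statistic']:.2f}, p = {entry['friedman_p']:.2g}")
if "nemenyi_p" in entry:
    p = entry["nemenyi_p"]
    print("Nemenyi p (IE predictor A vs close eluting): "
          f"{p.loc['ie_predictor_A', 'close_eluting']:.3g}")

wilcoxon = matrix_effect_test(study.peaks)
print("\nmatrix effects vs HPLC-grade water (Wilcoxon, Bonferroni-adjusted):")
for _, row in wilcoxon.iterrows():
    print(f"  {row['matrix']:<8s} {row['level']:<5s} n={row['n_pairs']:<4d} "
          f"p_adj = {row['p_adjusted']:.3g}")
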