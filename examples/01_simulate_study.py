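"""Generate a synthetic multi-laboratory study and inspect its design.

Each simulated laboratory receives the same 15 samples: six calibration
standards in clean water, three water matrices spiked with suspects at a
high level and a 10x dilution, and three blanks.  Peak areas follow a
multiplicative model (response factor x concentration x lab effect x
matrix effect x lognormal noise) with detection censoring.
"""

from ntsquant import StudyConfig, generate_study

config = StudyConfig(n_labs=4, seed=7)
study = generate_study(config)

roles = study.compounds["role"].value_counts()
print(f"compounds: {roles['calibrant']} calibrants, {roles['suspect']} suspects, "
      f"{roles['ilis']} internal standard(s)")
n_tp = study.compounds["parent_id"].notna().sum()
print(f"transformation products among suspects: {n_tp}")

per_lab = study.samples.groupby("dataset_id")["sample_id"].nunique()
print(f"samples per laboratory: {per_lab.min()}..{per_lab.max()}")
print(f"peak records across {config.n_labs} labs: {len(study.peaks)}")
print(f"true log10 response factors span "
      f"{study.compounds['log10_rf_true'].min():.2f}.."
      f"{study.compounds['log10_rf_true'].max():.2f}")

# The truth table holds the spiked concentration of every compound in every
# non-blank sample; it is the reference the accuracy evaluation uses.
high = study.truth[study.truth["level"] == "high"]
print(f"suspect spike levels (high) span {high['conc'].min():.2e}.."
      f"{high['conc'].max():.2e} mol/L")
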