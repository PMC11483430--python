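# Methods

## Generative model of the synthetic study

The generator emulates an interlaboratory NTS trial in which identical
sample sets are shipped to many laboratories and each lab analyzes them
with its own LC/ESI/HRMS workflow. A study is parameterized by
`StudyConfig`; the defaults reproduce the trial design: 40 datasets,
41 calibrants measured at six log-spaced levels from 8.49×10⁻¹⁰ to
8.90×10⁻⁶ mol/L (0.6–1000 µg/L-equivalent), 45 suspects spiked between
6.70×10⁻⁸ and 5.89×10⁻⁶ mol/L (drawn log-uniformly per compound) into
three water matrices and diluted 10×, one isotope-labeled internal
standard (ILIS) at 1.7×10⁻⁷ mol/L in every non-blank sample, three
blanks, and triplicate injections. Blanks carry no peak records — the
ILIS is spiked only into suspect and calibration samples — so the "15
samples per laboratory" design count lives in the generated sample
manifest.

A peak area is

```
area = RF_true · conc · lab_effect · matrix_effect · 10^ε,   ε ~ N(0, σ_area)
```

with, by default:

| parameter | default | meaning |
|---|---|---|
| `log10_rf_range` | [13, 15.5] | true response factors (area per mol/L), order-of-magnitude emulation of observed RF spans |
| `noise_sigma_log10_area` (σ_area) | 0.15 | multiplicative measurement noise, log₁₀ units |
| `lab_effect_sigma` | 0.3 | per-lab global response factor, log₁₀ units |
| `matrix_effect_sigma` | 0.1 | per-(lab, matrix, compound) factor, log₁₀ units; HPLC-grade water is fixed at 1 (matrix-free reference) |
| `censor_quantile` | 0.05 | per-lab detection censoring: areas below this quantile of the lab's areas are removed |
| `tp_fraction` | 0.6 | fraction of suspects that are transformation products |
| `tp_delta_sigma` | 1.0 | half-normal sd of the TP log₁₀ RF attenuation |
| `ie_predictor_sigma` / `_b` | 0.3 / 0.45 | sd of predictor A / B log IE noise |
| `rt_stretch_sigma` / `rt_shift_sigma` | 0.05 / 0.3 min | per-lab affine retention distortion |

Noise is multiplicative lognormal because peak areas span orders of
magnitude and the whole evaluation is ratio-scale (fold errors). A
majority of suspects are TPs linked to calibrant parents with attenuated
response (TPs are less hydrophobic and ionize worse), sharing 80% of the
parent's fingerprint bits and eluting earlier; this is what makes the
parent–TP and structural-similarity approaches systematically
underpredict. Predicted log IE is an exact affine image of true log₁₀ RF
plus Gaussian noise, one draw per compound per predictor — so at zero
predictor noise and zero measurement noise the IE approaches are exact,
and the two predictors emulate two external prediction platforms with
distinct error structure. The ILIS receives its own noise draw, making
normalization non-trivial; an optional `ilis_misintegration` fault
multiplies ILIS areas in the concentrated samples by 10 to reproduce a
documented integration failure mode.

Fingerprints are synthetic 256-bit vectors (density 0.125); no chemistry
engine is involved. Real-structure fingerprints can be supplied through
the compound-metadata path instead.

What the generator does *not* emulate: chromatographic peak shapes,
adducts and in-source fragments, compound degradation during shipping,
inter-compound correlation of matrix effects, and any systematic
(directional) matrix suppression — matrix factors are symmetric around 1,
so the matrix-effect test is exercised under a null by default. Passing
tests therefore demonstrate the correctness of the pipeline's arithmetic
and its qualitative behavior under a plausible error model, not
quantitative agreement with any particular instrument.

## Data-quality pipeline

**Normalization.** Each area is divided by the ILIS area of the same
(dataset, sample, replicate). A missing or non-positive ILIS is an error
unless the raw-area fallback is enabled (emulating workflows that skip
ILIS correction).

**Calibration fitting and linear-range trimming.** Replicate areas are
arithmetic-mean averaged per level; the line is ordinary least squares of
normalized area on concentration. Manual linearity inspection is replaced
by an algorithmic endpoint-trimming rule: while either the lowest or
highest remaining level is out of range, the worse endpoint is dropped and
the line refitted; curves left with fewer than three levels are unusable.
Endpoints-only trimming reflects the physics of the linear range
(saturation at the top, quantification limit at the bottom). An endpoint
is out of range when it deviates by more than 25% (relative) from **both**
the fitted line (|obs − pred|/|pred|) and proportional response (its
area/concentration ratio vs the geometric-mean ratio of the retained
levels). The double condition is deliberate: on six log-spaced levels the
OLS intercept is estimated at the scale of the top-level areas, so its
estimation noise alone dwarfs the lowest-level signal; judged by the
line-residual only, perfectly proportional noisy data would lose its
bottom levels until the curve died, discarding roughly three quarters of
calibrants at the default noise level. With the double condition, exact
lines (any intercept) are never trimmed, genuine saturation or a detector
floor still fails both checks, and ~97% of calibration curves survive the
default noise — matching a situation in which most calibrants remain
usable. The threshold (0.25) and the aggregation (arithmetic mean of
replicates) are configurable.

**Dead-time filter.** t₀ = ε·π·(d/2)²·L/F with porosity ε defaulting to
0.65 (typical total porosity of packed RP columns; configurable). All
records of a compound whose dataset-mean RT is strictly shorter than t₀
are removed; a compound at exactly t₀ is retained.

**Dilution-ratio filter.** Per (dataset, matrix, suspect), the ratio of
replicate-averaged areas undiluted/diluted is compared with [5, 20]
(theoretical value 10). Removal is strict ("below 5 or above 20"), so
ratios exactly at the bounds are kept. Compounds detected at a single
level are flagged, not filtered. Both filters decide from their input
records only, so dead-time and ratio filtering commute.

## Quantification

Surrogate quantification inverts the full calibration line,
c = (A − b)/m; negative results are flagged unquantifiable rather than
clipped, and a slope-only mode (c = A/m) mimics workflows that use the
plain area/RF ratio. Tie-breaks are deterministic: structural similarity
ties resolve to the smaller |ΔRT| then lexicographic id; equidistant
close-eluting ties resolve to the earlier-eluting calibrant. The
harmonization regresses log₁₀ RF on predicted log IE over calibrants with
usable, strictly positive slopes; non-positive-slope calibrants are
excluded and recorded (negative slopes entering a harmonization is a
known failure mode of unscreened data), and fewer than three usable
points makes the IE route unavailable. Unavailability of any approach is
a first-class result state — the Friedman stage needs to see incomplete
datasets to drop them.

## Evaluation

Fold error max(ĉ/c, c/ĉ) and log error log₁₀(ĉ/c) satisfy
fold = 10^|log| identically. Summaries report mean, median and the
linearly interpolated 95% quantile of fold error plus the percentage
within 10×. Outliers are Tukey-whisker flags (outside Q1 − 1.5·IQR,
Q3 + 1.5·IQR) per (dataset, approach) group — pooling samples and
compounds, mirroring a box-per-dataset-per-approach layout; groups
smaller than 4 produce no flags, and flags within the 10× band are not
counted. The per-compound outlier rate is 100·occurrences/opportunities,
where opportunities are (metric × approach × sample × dataset) cells in
which the compound was detected and quantified — "detection frequency" is
operationalized as the quantified-cell count. With 2 metrics,
5 approaches, 6 suspect samples and 40 datasets a fully detected compound
has exactly 2 400 opportunities.

The Friedman test runs per sample on the datasets × approaches matrix of
mean fold errors; datasets missing any approach are dropped first and
recorded. A fully tied matrix is reported as statistic 0, p = 1 (scipy's
tie correction is undefined there). Significant results (α = 0.05) are
followed by Nemenyi all-pairs comparisons implemented on the studentized
range distribution: |R̄ᵢ − R̄ⱼ|/√(k(k+1)/6n) referred to q/√2 with k
groups and infinite df. Matrix effects are tested with the Wilcoxon
signed-rank on replicate-averaged **areas** (not errors, to exclude the
quantification approach), pairing tap/surface against HPLC-grade water per
(dataset, compound) at each level separately, Bonferroni-adjusted over the
family of comparisons performed in the run (4 by default: 2 matrices × 2
levels); comparisons with fewer than 6 pairs are skipped with a reason.

## Problem sizes and determinism

All randomness flows from `StudyConfig.seed` through one
`numpy.random.Generator`; identical configurations produce byte-identical
serialized studies, and the pipeline manifest records the config hash and
file digests for replay verification. The test suite exercises the
full-design study (40 labs) only where the design counts themselves are
asserted; distributional properties run on 2–8-lab studies, the
qualitative approach-ranking check uses 50 seeds × 8 laboratories, and
the type-I-error check for the matrix test uses 100 seeds × 2
laboratories — sizes chosen to make the properties statistically decisive
while keeping each run small.

## Known limitations

* The RF–RT joint distribution, noise magnitudes and matrix-effect scale
  are order-of-magnitude emulations, not fits to measured data.
* Calibration is HPLC-water only (as in the emulated design); no
  matrix-matched calibration.
* Only protonated-species areas are modeled; adduct/in-source-fragment
  aggregation is out of scope.
* The CSV schema is a clean-room tidy format; it does not reproduce any
  particular lab's workbook layout.
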