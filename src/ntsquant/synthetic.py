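"""Synthetic multi-laboratory study generator.

Emulates the design of an interlaboratory non-target LC/ESI/HRMS trial:
each laboratory receives 15 samples — six calibration standards in clean
(HPLC-grade) water, three water matrices (HPLC, tap, surface) spiked with
suspects at a high level and a 10x dilution, and three matrix blanks.  An
isotope-labeled internal standard (ILIS) is spiked at a constant level into
every non-blank sample.

The generative model for a peak area is multiplicative:

    area = RF_true * conc * lab_effect * matrix_effect * 10^eps,
    eps ~ N(0, noise_sigma_log10_area)

with per-lab response effects, per-(lab, matrix, compound) matrix effects
(HPLC water fixed at 1: it is treated as a matrix-free medium), detection
censoring at a per-lab area quantile, and per-lab retention-time stretch and
shift.  A configurable fraction of suspects are transformation products
(TPs) linked to a calibrant parent; TPs ionize worse, so their response
factor is attenuated by 10^-delta with delta half-normal, and their
fingerprint shares a configurable fraction of the parent's bits.

Predicted log ionization efficiencies for two predictors (A and B) are the
true log IE — an affine image of true log10 RF — plus independent Gaussian
noise, one draw per compound per predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import (
    CALIBRATION_LEVELS,
    ConfigError,
    bits_to_fingerprint,
)

__all__ = ["StudyConfig", "SyntheticStudy", "generate_compounds", "generate_study"]

ILIS_ID = "ILIS_atrazine_d5"


@dataclass
class StudyConfig:
    """Configuration of a synthetic interlaboratory study.

    Defaults reproduce the trial design: 40 datasets, 41 calibrants at six
    log-spaced levels spanning 8.49e-10 to 8.90e-6 M (0.6–1000 ug/L
    equivalent), 45 suspects spiked between 6.70e-8 and 5.89e-6 M
    (14–780 ug/L) and diluted 10x, ILIS at ~1.7e-7 M, triplicate
    injections, and response factors spanning 10^13–10^15.5 normalized-area
    units per mol/L.
    """

    n_labs: int = 40
    n_calibrants: int = 41
    n_suspects: int = 45
    n_cal_levels: int = 6
    cal_conc_range: tuple[float, float] = (8.49e-10, 8.90e-6)  # mol/L
    suspect_conc_range: tuple[float, float] = (6.70e-8, 5.89e-6)  # mol/L, high
    dilution_factor: float = 10.0
    ilis_conc: float = 1.7e-7  # mol/L
    replicates: int = 3
    log10_rf_range: tuple[float, float] = (13.0, 15.5)
    rt_range: tuple[float, float] = (1.0, 25.0)  # minutes, gradient span
    # transformation products
    tp_fraction: float = 0.6
    tp_delta_sigma: float = 1.0  # half-normal sd of log10 RF attenuation
    # fingerprints
    fp_nbits: int = 256
    fp_density: float = 0.125
    fp_parent_overlap: float = 0.8
    # ionization-efficiency predictors: log10_rf = ie_slope*log_ie + ie_intercept
    ie_slope: float = 1.2
    ie_intercept: float = 14.0
    ie_predictor_sigma: float = 0.3  # predictor A, log10 units
    ie_predictor_sigma_b: float = 0.45  # predictor B
    # noise terms
    noise_sigma_log10_area: float = 0.15
    matrix_effect_sigma: float = 0.1  # log10 units; tap/surface only
    lab_effect_sigma: float = 0.3  # log10 units
    rt_stretch_sigma: float = 0.05
    rt_shift_sigma: float = 0.3  # minutes
    censor_quantile: float = 0.05
    ilis_misintegration: bool = False
    seed: int = 1

    def validate(self) -> "StudyConfig":
        if self.n_labs < 1:
            raise ConfigError("n_labs must be >= 1")
        if self.n_calibrants < 1 or self.n_suspects < 1:
            raise ConfigError("n_calibrants and n_suspects must be >= 1")
        if not self.dilution_factor > 1:
            raise ConfigError("dilution_factor must be > 1")
        if self.replicates not in (1, 2, 3):
            raise ConfigError("replicates must be 1, 2 or 3")
        for name in ("cal_conc_range", "suspect_conc_range", "log10_rf_range", "rt_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} must be an ordered interval")
        if self.cal_conc_range[0] <= 0 or self.suspect_conc_range[0] <= 0:
            raise ConfigError("concentration ranges must be positive")
        if not 0 <= self.tp_fraction <= 1:
            raise ConfigError("tp_fraction must be in [0, 1]")
        if not 0 <= self.censor_quantile < 1:
            raise ConfigError("censor_quantile must be in [0, 1)")
        for name in (
            "tp_delta_sigma",
            "ie_predictor_sigma",
            "ie_predictor_sigma_b",
            "noise_sigma_log10_area",
            "matrix_effect_sigma",
            "lab_effect_sigma",
            "rt_stretch_sigma",
            "rt_shift_sigma",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.fp_density < 1 or not 0 <= self.fp_parent_overlap <= 1:
            raise ConfigError("fingerprint parameters out of range")
        return self

    def noiseless(self, **overrides) -> "StudyConfig":
        """Copy of this config with every stochastic nuisance term disabled
        (measurement noise, matrix effects, censoring, IE-predictor noise).
        Lab effects and TP attenuation are structural and kept unless
        overridden."""
        kw = asdict(self)
        kw.update(
            noise_sigma_log10_area=0.0,
            matrix_effect_sigma=0.0,
            censor_quantile=0.0,
            ie_predictor_sigma=0.0,
            ie_predictor_sigma_b=0.0,
        )
        kw.update(overrides)
        return StudyConfig(**kw)

    def calibration_levels(self) -> np.ndarray:
        """The six (by default) log-spaced calibration concentrations, mol/L."""
        lo, hi = self.cal_conc_range
        return np.logspace(np.log10(lo), np.log10(hi), self.n_cal_levels)


@dataclass
class SyntheticStudy:
    """A generated study: compound metadata (with hidden truth columns),
    per-lab sample manifest, the pooled peak table, and the truth table of
    spiked concentrations."""

    config: StudyConfig
    compounds: pd.DataFrame
    samples: pd.DataFrame  # dataset_id, sample_id, matrix, level
    peaks: pd.DataFrame
    truth: pd.DataFrame  # sample_id, compound_id, conc (mol/L), level, matrix
    lab_effects: pd.DataFrame = field(default=None)

    def peaks_for(self, dataset_id: str) -> pd.DataFrame:
        return self.peaks[self.peaks["dataset_id"] == dataset_id].reset_index(drop=True)


def _random_fingerprints(rng, n, nbits, density):
    return (rng.random((n, nbits)) < density).astype(np.uint8)


def generate_compounds(config: StudyConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate the study's compound set: calibrants, suspects (some of them
    TPs linked to calibrant parents) and one ILIS.

    Returns a DataFrame with public metadata columns (id, role, rt,
    fingerprint, parent_id, mw, log_ie_A, log_ie_B) plus the hidden truth
    column ``log10_rf_true``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_cal, n_sus = config.n_calibrants, config.n_suspects
    n_tp = int(round(config.tp_fraction * n_sus))
    if n_tp > n_sus:
        raise ConfigError("more TP links requested than suspects available")

    lo_rf, hi_rf = config.log10_rf_range
    lo_rt, hi_rt = config.rt_range

    cal_ids = [f"C{i:02d}" for i in range(1, n_cal + 1)]
    sus_ids = [f"S{i:02d}" for i in range(1, n_sus + 1)]

    cal_rf = rng.uniform(lo_rf, hi_rf, n_cal)
    cal_rt = rng.uniform(lo_rt, hi_rt, n_cal)
    sus_rf = rng.uniform(lo_rf, hi_rf, n_sus)
    sus_rt = rng.uniform(lo_rt, hi_rt, n_sus)
    cal_fp = _random_fingerprints(rng, n_cal, config.fp_nbits, config.fp_density)
    sus_fp = _random_fingerprints(rng, n_sus, config.fp_nbits, config.fp_density)

    # first n_tp suspects become transformation products of random parents
    parent_of = [None] * n_sus
    parent_idx = rng.integers(0, n_cal, n_tp)
    delta = np.abs(rng.normal(0.0, config.tp_delta_sigma, n_tp))
    for j in range(n_tp):
        p = int(parent_idx[j])
        parent_of[j] = cal_ids[p]
        sus_rf[j] = cal_rf[p] - delta[j]  # TPs ionize worse than parents
        # TPs are less hydrophobic: elute earlier than the parent
        sus_rt[j] = max(lo_rt * 0.5, cal_rt[p] * rng.uniform(0.5, 0.95))
        keep = rng.random(config.fp_nbits) < config.fp_parent_overlap
        extra = rng.random(config.fp_nbits) < config.fp_density * (
            1.0 - config.fp_parent_overlap
        )
        sus_fp[j] = ((cal_fp[p] & keep) | extra).astype(np.uint8)

    ilis_rf = np.array([0.5 * (lo_rf + hi_rf)])
    ilis_rt = np.array([0.5 * (lo_rt + hi_rt)])

    ids = cal_ids + sus_ids + [ILIS_ID]
    roles = ["calibrant"] * n_cal + ["suspect"] * n_sus + ["ilis"]
    rf = np.concatenate([cal_rf, sus_rf, ilis_rf])
    rt = np.concatenate([cal_rt, sus_rt, ilis_rt])
    fps = [bits_to_fingerprint(b) for b in cal_fp] + [
        bits_to_fingerprint(b) for b in sus_fp
    ] + [None]
    parents = [None] * n_cal + parent_of + [None]
    mw = rng.uniform(100.0, 500.0, len(ids))

    log_ie_true = (rf - config.ie_intercept) / config.ie_slope
    log_ie_a = log_ie_true + rng.normal(0.0, config.ie_predictor_sigma, len(ids))
    log_ie_b = log_ie_true + rng.normal(0.0, config.ie_predictor_sigma_b, len(ids))

    return pd.DataFrame(
        {
            "id": ids,
            "role": roles,
            "rt": rt,
            "fingerprint": fps,
            "parent_id": parents,
            "mw": mw,
            "log_ie_A": log_ie_a,
            "log_ie_B": log_ie_b,
            "log10_rf_true": rf,
            "log_ie_true": log_ie_true,
        }
    )


def _sample_manifest() -> pd.DataFrame:
    """The 15 sample entities each laboratory receives."""
    rows = [(f"cal_{i}", "hplc", CALIBRATION_LEVELS[i - 1]) for i in range(1, 7)]
    for s, m in (("s1", "hplc"), ("s2", "tap"), ("s3", "surface")):
        rows.append((f"{s}a", m, "high"))
        rows.append((f"{s}b", m, "low"))
    rows += [("b1", "hplc", "blank"), ("b2", "tap", "blank"), ("b3", "surface", "blank")]
    return pd.DataFrame(rows, columns=["sample_id", "matrix", "level"])


def _truth_table(config: StudyConfig, compounds: pd.DataFrame, rng) -> pd.DataFrame:
    """Spiked concentration of every compound in every (non-blank) sample.
    Samples are identical across laboratories: one truth table serves all."""
    manifest = _sample_manifest()
    cal_levels = config.calibration_levels()
    cal = compounds[compounds["role"] == "calibrant"]
    sus = compounds[compounds["role"] == "suspect"]

    lo, hi = config.suspect_conc_range
    high_conc = 10 ** rng.uniform(np.log10(lo), np.log10(hi), len(sus))

    rows = []
    for _, smp in manifest.iterrows():
        if smp["level"] == "blank":
            continue
        if smp["level"].startswith("calibration"):
            lvl = int(smp["level"].rsplit("_", 1)[1])
            for cid in cal["id"]:
                rows.append((smp["sample_id"], cid, cal_levels[lvl - 1]))
        else:
            dil = 1.0 if smp["level"] == "high" else config.dilution_factor
            for cid, c in zip(sus["id"], high_conc):
                rows.append((smp["sample_id"], cid, c / dil))
        rows.append((smp["sample_id"], ILIS_ID, config.ilis_conc))
    truth = pd.DataFrame(rows, columns=["sample_id", "compound_id", "conc"])
    return truth.merge(manifest, on="sample_id")


def generate_study(
    config: StudyConfig, compounds: pd.DataFrame | None = None
) -> SyntheticStudy:
    """Generate a full multi-laboratory study.

    Deterministic in (config, compounds): the same configuration yields a
    byte-identical serialized study.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if compounds is None:
        compounds = generate_compounds(config, seed=rng.integers(0, 2**31))

    truth = _truth_table(config, compounds, rng)
    manifest = _sample_manifest()

    rf_true = 10.0 ** compounds.set_index("id")["log10_rf_true"]
    rt_nominal = compounds.set_index("id")["rt"]

    lab_rows, peak_frames, samples_frames = [], [], []
    base = truth[truth["level"] != "blank"].copy()
    n_base = len(base)

    for k in range(1, config.n_labs + 1):
        lab = f"lab{k:02d}"
        lab_effect = 10.0 ** rng.normal(0.0, config.lab_effect_sigma)
        stretch = rng.normal(1.0, config.rt_stretch_sigma)
        shift = rng.normal(0.0, config.rt_shift_sigma)
        misint = config.ilis_misintegration
        lab_rows.append((lab, lab_effect, stretch, shift))

        # per-(matrix, compound) matrix effects; HPLC water fixed at 1
        me = {}
        for m in ("tap", "surface"):
            me[m] = pd.Series(
                10.0 ** rng.normal(0.0, config.matrix_effect_sigma, len(compounds)),
                index=compounds["id"].values,
            )

        mfac = np.ones(n_base)
        for m in ("tap", "surface"):
            sel = base["matrix"].values == m
            if sel.any():
                mfac[sel] = me[m].reindex(base.loc[sel, "compound_id"]).values

        mean_area = rf_true.reindex(base["compound_id"]).values * base[
            "conc"
        ].values * lab_effect * mfac

        reps = []
        for r in range(1, config.replicates + 1):
            eps = rng.normal(0.0, config.noise_sigma_log10_area, n_base)
            rep = base[["sample_id", "matrix", "level", "compound_id"]].copy()
            rep["replicate"] = r
            rep["area"] = mean_area * 10.0**eps
            reps.append(rep)
        peaks = pd.concat(reps, ignore_index=True)

        if misint:
            # faulty ILIS integration: areas track the sample level (10x in
            # the concentrated samples), the failure mode this normalization
            # is meant to catch
            bad = (peaks["compound_id"] == ILIS_ID) & (peaks["level"] == "high")
            peaks.loc[bad, "area"] *= 10.0

        if config.censor_quantile > 0:
            thr = np.quantile(peaks["area"].values, config.censor_quantile)
            peaks = peaks[peaks["area"] >= thr]

        peaks = peaks.copy()
        peaks["dataset_id"] = lab
        peaks["rt"] = (
            rt_nominal.reindex(peaks["compound_id"]).values * stretch + shift
        ).clip(min=0.0)
        known = truth.set_index(["sample_id", "compound_id"])["conc"]
        idx = pd.MultiIndex.from_arrays([peaks["sample_id"], peaks["compound_id"]])
        conc = known.reindex(idx).values
        is_known = peaks["level"].str.startswith("calibration").values | (
            peaks["compound_id"] == ILIS_ID
        )
        peaks["known_conc"] = np.where(is_known, conc, np.nan)
        peak_frames.append(peaks)

        smp = manifest.copy()
        smp.insert(0, "dataset_id", lab)
        samples_frames.append(smp)

    peaks = pd.concat(peak_frames, ignore_index=True)[
        [
            "dataset_id",
            "sample_id",
            "matrix",
            "level",
            "replicate",
            "compound_id",
            "rt",
            "area",
            "known_conc",
        ]
    ]
    samples = pd.concat(samples_frames, ignore_index=True)
    lab_effects = pd.DataFrame(
        lab_rows, columns=["dataset_id", "response_factor_effect", "rt_stretch", "rt_shift"]
    )
    return SyntheticStudy(
        config=config,
        compounds=compounds,
        samples=samples,
        peaks=peaks,
        truth=truth,
        lab_effects=lab_effects,
    )
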