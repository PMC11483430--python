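import pandas as pd
import pytest

from ntsquant.evaluate import build_accuracy
from ntsquant.qc import fit_all_calibrations, normalize_peaks, ratio_filter
from ntsquant.quantify import run_all_approaches
from ntsquant.synthetic import StudyConfig, generate_study


@pytest.fixture(scope="session")
def noiseless_study():
    """Two-lab study with every stochastic nuisance term disabled."""
    return generate_study(StudyConfig(n_labs=2, seed=11).noiseless())


@pytest.fixture(scope="session")
def noisy_study():
    """Three-lab study under the default noise model."""
    return generate_study(StudyConfig(n_labs=3, seed=5))


def run_quantification(study):
    """QC + quantification on a generated study; returns (norm peaks, fits,
    quant results, accuracy table)."""
    norm = normalize_peaks(study.peaks)
    fits = fit_all_calibrations(norm)
    kept, _ = ratio_filter(norm)
    quant = run_all_approaches(kept, study.compounds, fits)
    accuracy = build_accuracy(quant, study.truth)
    return norm, fits, quant, accuracy


@pytest.fixture(scope="session")
def noiseless_results(noiseless_study):
    return run_quantification(noiseless_study)


@pytest.fixture(scope="session")
def noisy_results(noisy_study):
    return run_quantification(noisy_study)


def toy_accuracy(rows) -> pd.DataFrame:
    """Accuracy-table frame from (dataset, sample, approach, compound,
    fold_error, log_error) tuples; matrix/level filled with defaults."""
    df = pd.DataFrame(
        rows,
        columns=[
            "dataset_id",
            "sample_id",
            "approach",
            "compound_id",
            "fold_error",
            "log_error",
        ],
    )
    df["matrix"] = "hplc"
    df["level"] = "high"
    df["estimated_conc"] = df["fold_error"] * 1e-7
    df["spiked_conc"] = 1e-7
    return df
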