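import numpy as np
import pandas as pd
import pytest

from ntsquant.datamodel import CalibrationFit, bits_to_fingerprint
from ntsquant.quantify import (
    assign_close_eluting,
    assign_most_similar,
    assign_parent,
    harmonize_ie,
    jaccard_similarity,
    quantify_by_ie,
    quantify_by_surrogate,
    run_all_approaches,
)


def _fit(cid, slope=2.0, intercept=0.0, usable=True):
    return CalibrationFit(
        compound_id=cid,
        slope=slope,
        intercept=intercept,
        n_used=6,
        r_squared=1.0,
        usable=usable,
    )


def _fp(bit_positions, n=256):
    bits = np.zeros(n, dtype=np.uint8)
    bits[list(bit_positions)] = 1
    return bits_to_fingerprint(bits)


class TestAssignments:
    def test_parent_assignment_and_unavailable_when_parent_filtered(self):
        pairing = {"S01": "C01"}
        fits = {"C01": _fit("C01")}
        asg = assign_parent("S01", pairing, fits)
        assert asg.surrogate_id == "C01" and asg.rule == "parent"
        assert assign_parent("S01", pairing, {"C01": _fit("C01", usable=False)}) is None
        assert assign_parent("S99", pairing, fits) is None

    def test_designated_swapped_pair_honored_as_listed(self):
        # a suspect that is chemically the parent may still be listed with
        # its TP as surrogate; the listed pairing wins
        pairing = {"S_metformin": "C_guanylurea"}
        fits = {"C_guanylurea": _fit("C_guanylurea")}
        asg = assign_parent("S_metformin", pairing, fits)
        assert asg.surrogate_id == "C_guanylurea"

    def test_identical_fingerprint_wins_with_score_one(self):
        compounds = pd.DataFrame(
            {
                "id": ["S01", "C01", "C02"],
                "role": ["suspect", "calibrant", "calibrant"],
                "rt": [5.0, 8.0, 2.0],
                "fingerprint": [_fp(range(10)), _fp(range(10)), _fp(range(100, 130))],
            }
        )
        fits = {"C01": _fit("C01"), "C02": _fit("C02")}
        asg = assign_most_similar("S01", compounds, fits)
        assert asg.surrogate_id == "C01"
        assert asg.score == pytest.approx(1.0)

    def test_jaccard_hand_computation_selects_higher_overlap(self):
        # suspect has 16 bits; A shares 8 of its 16, B shares 4 of its 16
        s = set(range(16))
        a = set(range(8)) | set(range(100, 108))
        b = set(range(4)) | set(range(200, 212))
        assert jaccard_similarity(
            np.isin(np.arange(256), list(s)), np.isin(np.arange(256), list(a))
        ) == pytest.approx(8 / 24)
        compounds = pd.DataFrame(
            {
                "id": ["S01", "A", "B"],
                "role": ["suspect", "calibrant", "calibrant"],
                "rt": [5.0, 5.0, 5.0],
                "fingerprint": [_fp(s), _fp(a), _fp(b)],
            }
        )
        fits = {"A": _fit("A"), "B": _fit("B")}
        assert assign_most_similar("S01", compounds, fits).surrogate_id == "A"

    def test_similarity_tie_broken_by_smaller_rt_gap(self):
        fp = _fp(range(20))
        compounds = pd.DataFrame(
            {
                "id": ["S01", "C01", "C02"],
                "role": ["suspect", "calibrant", "calibrant"],
                "rt": [5.0, 9.0, 4.8],
                "fingerprint": [fp, fp, fp],
            }
        )
        fits = {"C01": _fit("C01"), "C02": _fit("C02")}
        assert assign_most_similar("S01", compounds, fits).surrogate_id == "C02"

    def test_missing_fingerprint_makes_approach_unavailable(self):
        compounds = pd.DataFrame(
            {
                "id": ["S01", "C01"],
                "role": ["suspect", "calibrant"],
                "rt": [5.0, 6.0],
                "fingerprint": [None, _fp(range(5))],
            }
        )
        assert assign_most_similar("S01", compounds, {"C01": _fit("C01")}) is None

    def test_close_eluting_nearest_and_tie_to_earlier(self):
        fits = {"C01": _fit("C01"), "C02": _fit("C02")}
        rts = pd.Series({"S01": 5.0, "C01": 4.8, "C02": 5.3})
        assert assign_close_eluting("S01", fits, rts).surrogate_id == "C01"
        rts_tie = pd.Series({"S01": 5.0, "C01": 4.8, "C02": 5.2})
        assert assign_close_eluting("S01", fits, rts_tie).surrogate_id == "C01"

    def test_close_eluting_recomputed_per_dataset(self, noisy_results):
        """Dataset-specific RT shifts may give the same suspect different
        surrogates in different laboratories."""
        _, _, quant, _ = noisy_results
        ce = quant[(quant["approach"] == "close_eluting") & quant["surrogate_id"].notna()]
        per_suspect = ce.groupby("compound_id")["surrogate_id"].nunique()
        assert (per_suspect >= 1).all()  # well-formed per dataset
        # assignments depend only on RTs: same dataset, same suspect -> one surrogate
        per_ds = ce.groupby(["dataset_id", "compound_id"])["surrogate_id"].nunique()
        assert (per_ds == 1).all()


class TestQuantification:
    def test_surrogate_line_inversion(self):
        assert quantify_by_surrogate(20.0, _fit("C", slope=2.0)) == 10.0

    def test_area_below_intercept_unquantifiable(self):
        fit = _fit("C", slope=2.0, intercept=5.0)
        assert quantify_by_surrogate(1.0, fit) is None

    def test_slope_only_mode_divides_by_rf(self):
        fit = _fit("C", slope=2.0, intercept=5.0)
        assert quantify_by_surrogate(1.0, fit, slope_only=True) == 0.5

    def test_ie_quantification_arithmetic(self):
        # harmonization yielding RF_pred = 10 at log_ie = 1
        from ntsquant.datamodel import Harmonization

        harm = Harmonization(slope=1.0, intercept=0.0, n_calibrants_used=5, r_squared=1.0)
        assert quantify_by_ie(50.0, 1.0, harm) == pytest.approx(5.0)

    def test_ie_estimate_decreases_with_log_ie(self):
        from ntsquant.datamodel import Harmonization

        harm = Harmonization(slope=0.8, intercept=2.0, n_calibrants_used=5, r_squared=1.0)
        grid = np.linspace(-2, 3, 25)
        est = [quantify_by_ie(100.0, g, harm) for g in grid]
        assert all(a > b for a, b in zip(est, est[1:]))


class TestHarmonization:
    def test_exact_affine_relation_recovered(self):
        log_ie = pd.Series({f"C{i}": float(i) for i in range(5)})
        fits = {
            f"C{i}": _fit(f"C{i}", slope=10 ** (1.0 * i + 2.0)) for i in range(5)
        }
        harm = harmonize_ie(fits, log_ie)
        assert harm.slope == pytest.approx(1.0, abs=1e-9)
        assert harm.intercept == pytest.approx(2.0, abs=1e-9)
        assert harm.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_negative_slope_calibrant_excluded_and_recorded(self):
        log_ie = pd.Series({f"C{i}": float(i) for i in range(6)})
        fits = {
            f"C{i}": _fit(f"C{i}", slope=10 ** (1.0 * i + 2.0)) for i in range(5)
        }
        fits["C5"] = _fit("C5", slope=-3.0)
        harm = harmonize_ie(fits, log_ie)
        assert harm.excluded_ids == ("C5",)
        assert harm.n_calibrants_used == 5
        assert harm.slope == pytest.approx(1.0, abs=1e-9)

    def test_fewer_than_three_points_unavailable(self):
        log_ie = pd.Series({"C0": 0.0, "C1": 1.0})
        fits = {"C0": _fit("C0"), "C1": _fit("C1")}
        assert harmonize_ie(fits, log_ie) is None

    def test_noisy_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 12)
        y = 0.9 * x + 3.0 + rng.normal(0, 0.2, 12)
        ids = [f"C{i:02d}" for i in range(12)]
        log_ie = pd.Series(dict(zip(ids, x)))
        fits = {cid: _fit(cid, slope=10.0**yi) for cid, yi in zip(ids, y)}
        harm = harmonize_ie(fits, log_ie)
        # closed-form normal equations
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert harm.slope == pytest.approx(beta[0], rel=1e-9)
        assert harm.intercept == pytest.approx(beta[1], rel=1e-9)


class TestRunAllApproaches:
    def _toy(self):
        fp = _fp(range(12))
        compounds = pd.DataFrame(
            {
                "id": ["C01", "C02", "S01", "S02", "S03"],
                "role": ["calibrant", "calibrant", "suspect", "suspect", "suspect"],
                "rt": [4.0, 9.0, 5.0, 6.0, 7.0],
                "fingerprint": [fp, _fp(range(50, 60)), fp, _fp(range(12, 24)), None],
                "parent_id": [None, None, "C01", None, None],
                "log_ie_A": [0.0, 1.0, 0.5, 0.7, np.nan],
                "log_ie_B": [0.0, 1.0, 0.5, 0.7, np.nan],
            }
        )
        rows = []
        for cid, rt in [("C01", 4.0), ("C02", 9.0)]:
            for lvl, conc in enumerate([1e-8, 1e-7, 1e-6], start=1):
                rows.append(
                    ("lab01", f"cal_{lvl}", "hplc", f"calibration_{lvl}", 1, cid, rt,
                     conc * 1e8, conc)
                )
        for sid, rt in [("S01", 5.0), ("S02", 6.0), ("S03", 7.0)]:
            rows.append(("lab01", "s1a", "hplc", "high", 1, sid, rt, 50.0, np.nan))
        peaks = pd.DataFrame(
            rows,
            columns=[
                "dataset_id", "sample_id", "matrix", "level", "replicate",
                "compound_id", "rt", "area", "known_conc",
            ],
        )
        peaks["norm_area"] = peaks["area"]
        fits = {"lab01": {"C01": _fit("C01", slope=1e8), "C02": _fit("C02", slope=1e8)}}
        return compounds, peaks, fits

    def test_result_count_matches_exhaustive_enumeration(self):
        compounds, peaks, fits = self._toy()
        quant = run_all_approaches(peaks, compounds, fits)
        # brute-force availability: S01 all 5; S02 has no parent (4);
        # S03 has neither fingerprint nor log IE (close eluting only);
        # harmonization needs >= 3 calibrants -> IE unavailable for everyone
        expect_available = {
            "S01": {"parent_tp", "structural_similarity", "close_eluting"},
            "S02": {"structural_similarity", "close_eluting"},
            "S03": {"close_eluting"},
        }
        assert len(quant) == 3 * 5  # one row per suspect x approach, always
        avail = quant[~quant["unquantifiable"]]
        got = {
            sid: set(grp["approach"])
            for sid, grp in avail.groupby("compound_id")
        }
        assert got == expect_available

    def test_unavailability_is_recorded_not_dropped(self):
        compounds, peaks, fits = self._toy()
        quant = run_all_approaches(peaks, compounds, fits)
        missing_parent = quant[
            (quant["compound_id"] == "S02") & (quant["approach"] == "parent_tp")
        ]
        assert len(missing_parent) == 1
        assert bool(missing_parent["unquantifiable"].iloc[0])
        assert "no surrogate" in missing_parent["provenance"].iloc[0]


class TestNoiselessRecovery:
    def test_calibrant_self_quantification_recovers_known_conc(self, noiseless_results):
        norm, fits, _, _ = noiseless_results
        cal = norm[norm["level"].str.startswith("calibration")]
        means = cal.groupby(["dataset_id", "compound_id", "known_conc"])[
            "norm_area"
        ].mean()
        for (ds, cid, conc), area in means.items():
            est = quantify_by_surrogate(area, fits[ds][cid])
            assert est == pytest.approx(conc, rel=1e-9)

    def test_surrogate_fold_error_equals_rf_ratio_of_pair(
        self, noiseless_study, noiseless_results
    ):
        """With no noise, the whole error of surrogate quantification is the
        suspect/surrogate response-factor gap."""
        _, _, _, acc = noiseless_results
        rf = noiseless_study.compounds.set_index("id")["log10_rf_true"]
        sur = acc[acc["approach"].isin(("parent_tp", "structural_similarity", "close_eluting"))]
        sur = sur[sur["surrogate_id"].notna()]
        expected = 10.0 ** (rf[sur["compound_id"]].values - rf[sur["surrogate_id"]].values)
        expected = np.maximum(expected, 1.0 / expected)
        np.testing.assert_allclose(sur["fold_error"], expected, rtol=1e-6)

    def test_ie_approaches_exact_in_collinear_limit(self, noiseless_results):
        _, _, _, acc = noiseless_results
        ie = acc[acc["approach"].isin(("ie_predictor_A", "ie_predictor_B"))]
        assert len(ie) > 0
        np.testing.assert_allclose(ie["fold_error"], 1.0, atol=1e-9)
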