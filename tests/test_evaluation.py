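"""Evaluation framework: oracle equivalence, partitioning, self-consistency."""

import numpy as np
import pandas as pd
import pytest

import ebmscale as eb
from ebmscale import CohortSpec
from ebmscale.evaluation import _slope_ci


def brute_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    cx, cy = x - x.mean(), y - y.mean()
    return float(np.sum(cx * cy) / np.sqrt(np.sum(cx**2) * np.sum(cy**2)))


class TestOracles:
    """Closed-form statistics match brute-force formulas to 1e-12."""

    def test_through_origin_slope_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 10, 17)
        y = 2.5 * x + rng.normal(0, 1, 17)
        assert eb.through_origin_slope(x, y) == pytest.approx(
            np.sum(x * y) / np.sum(x * x), abs=1e-12
        )

    def test_cohens_d_six_point_toy_table(self):
        a = np.array([10.0, 12.0, 11.0])
        b = np.array([8.0, 9.0, 10.0])
        pooled = np.sqrt(((2) * np.var(a, ddof=1) + (2) * np.var(b, ddof=1)) / 4)
        assert eb.cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled, abs=1e-12)

    def test_cohens_d_zero_pooled_variance_undefined(self):
        assert np.isnan(eb.cohens_d([3.0, 3.0], [5.0, 5.0]))

    def test_bin_correlations_match_brute_force(self, small_healthy):
        table = eb.size_independence(small_healthy, scaler="mass")
        df = small_healthy.with_derived()
        from ebmscale.evaluation import MEN_WL_EDGES, WOMEN_WL_EDGES, _assign_bins, _bin_labels

        for _, row in table.head(20).iterrows():
            if not np.isfinite(row["r"]):
                continue
            edges = MEN_WL_EDGES if row["sex"] == "male" else WOMEN_WL_EDGES
            labels = _bin_labels(edges)
            sub = df[df["sex"] == row["sex"]]
            idx = _assign_bins(sub["wl_mets"].to_numpy(), edges)
            sel = sub[idx == labels.index(row["wl_bin"])]
            expected = brute_pearson(
                sel["vo2peak_ml_min"] / sel["mass_kg"], sel["mass_kg"]
            )
            assert row["r"] == pytest.approx(expected, abs=1e-12)


class TestSizeIndependence:
    def test_partition_covers_cohort(self, small_healthy):
        table = eb.size_independence(small_healthy, scaler="ebm")
        assert table["n"].sum() == len(small_healthy)
        for sex in ("male", "female"):
            assert table.loc[table["sex"] == sex, "n"].sum() == (
                small_healthy.df["sex"] == sex
            ).sum()

    def test_mass_indexing_is_size_dependent_ebm_is_not(self, default_healthy):
        mass_tab = eb.size_independence(default_healthy, scaler="mass")
        ebm_tab = eb.size_independence(default_healthy, scaler="ebm")
        valid = mass_tab["r"].notna()
        assert (mass_tab.loc[valid, "r"] < 0).sum() > valid.sum() / 2
        assert int(ebm_tab["significant"].sum()) == 0

    def test_single_bin_noiseless_ebm_indexing_uncorrelated(self):
        # disable the age links so workload is fully independent of EBM;
        # with σ=0, VO2/EBM = 11·WL exactly and the within-sex correlation
        # is pure sampling noise, bounded by ~3.5/sqrt(n)
        spec = CohortSpec.healthy(
            n=500, sigma_log=0.0, age_speed_slope=0.0, age_hrr_slope=0.0
        )
        cohort = eb.generate_cohort(spec, seed=9)
        table = eb.size_independence(
            cohort, scaler="ebm", bins={"male": [1e9], "female": [1e9]}
        )
        first = table[table["n"] > 0]
        bound = 3.5 / np.sqrt(first["n"].astype(float))
        assert (first["r"].abs() < bound).all()

    def test_degenerate_proportional_bin_reports_nan(self):
        df = eb.generate_cohort(CohortSpec.healthy(n=50, sigma_log=0.0), seed=9).df.copy()
        df["vo2peak_ml_min"] = 3.0 * df["mass_kg"]  # indexed value exactly constant
        with pytest.warns(UserWarning, match="zero variance|n="):
            table = eb.size_independence(
                eb.Cohort(df), scaler="mass", bins={"male": [1e9], "female": [1e9]}
            )
        assert table.loc[table["n"] > 2, "r"].isna().all()

    def test_tiny_bin_warns_not_raises(self):
        df = eb.generate_cohort(CohortSpec.healthy(n=6), seed=1).df
        with pytest.warns(UserWarning, match="n="):
            table = eb.size_independence(eb.Cohort(df), scaler="mass")
        assert not table.empty


class TestCalibration:
    def test_identity_prediction_gives_unit_slopes(self):
        cohort = eb.generate_cohort(CohortSpec.healthy(n=800, sigma_log=0.0), seed=4)
        report = eb.calibration_slopes(cohort)
        assert np.allclose(report.table["slope"], 1.0, atol=1e-12)
        assert report.overall_slope == pytest.approx(1.0, abs=1e-12)

    def test_partition_covers_cohort(self, default_healthy):
        report = eb.calibration_slopes(default_healthy)
        assert report.table["n"].sum() == len(default_healthy)

    def test_all_cells_calibrated_on_default_data(self, default_healthy):
        report = eb.calibration_slopes(default_healthy)
        assert len(report.table) == 18
        assert ((report.table["slope"] - 1.0).abs() < 0.05).all()

    def test_constructed_hf_factor_recovered(self):
        hf = eb.generate_cohort(CohortSpec.hf(n=1007, hf_slope_factor=0.9), seed=1)
        report = eb.calibration_slopes(hf)
        assert report.overall_slope == pytest.approx(0.90, abs=0.02)

    def test_slope_ci_covers_point_estimate(self, small_healthy):
        report = eb.calibration_slopes(small_healthy)
        ok = report.table["slope_se"].notna()
        assert (report.table.loc[ok, "ci_low"] <= report.table.loc[ok, "slope"]).all()
        assert (report.table.loc[ok, "slope"] <= report.table.loc[ok, "ci_high"]).all()

    def test_mass_standard_model_runs(self, small_healthy):
        report = eb.calibration_slopes(small_healthy, model="mass_standard")
        assert (report.table["slope"] > 0).all()


class TestContrasts:
    def test_identical_groups_ratio_100_d_zero(self):
        df = eb.generate_cohort(CohortSpec.healthy(n=400), seed=5).with_derived()
        vals = df["vo2peak_ml_min"] / (3.5 * df["mass_kg"])
        assert eb.cohens_d(vals, vals) == pytest.approx(0.0, abs=1e-12)
        assert float(vals.mean() / vals.mean() * 100) == 100.0

    def test_ebm_standard_shrinks_sex_gap(self, default_healthy):
        con = eb.subgroup_contrasts(default_healthy)
        sex = con[con["contrast"] == "men_vs_women_bmi_lt_25"].set_index("standard")
        assert abs(sex.loc["ebm", "cohens_d"]) < abs(sex.loc["mass", "cohens_d"])

    def test_report_structure(self, small_healthy):
        con = eb.subgroup_contrasts(small_healthy)
        assert set(con["standard"]) == {"mass", "ebm"}
        assert len(con) == 6
        assert (con["ratio_pct"] > 0).all()


class TestHfSlopes:
    def test_equal_cohorts_ratio_one(self, small_healthy):
        res = eb.hf_slope_analysis(small_healthy, small_healthy)
        assert res["slope_ratio"] == pytest.approx(1.0, abs=1e-12)
        assert not res["hf_slope_lower"]

    def test_constructed_factor_detected(self, default_healthy):
        hf = eb.generate_cohort(CohortSpec.hf(n=1007, hf_slope_factor=0.9), seed=1)
        res = eb.hf_slope_analysis(default_healthy, hf)
        assert res["hf_slope_lower"]
        assert res["slope_ratio"] == pytest.approx(0.90, abs=0.02)

    def test_ratio_stable_across_cohort_sizes(self):
        ratios = []
        for n in (500, 2000):
            healthy = eb.generate_cohort(CohortSpec.healthy(n=n), seed=2)
            hf = eb.generate_cohort(CohortSpec.hf(n=n, hf_slope_factor=0.9), seed=3)
            ratios.append(eb.hf_slope_analysis(healthy, hf)["slope_ratio"])
        assert abs(ratios[0] - ratios[1]) < 0.03


class TestWorkloadComparison:
    def test_rest_intercepts(self):
        assert eb.workload_ebm(0, 0, 0) == 2.0
        assert eb.workload_kokkinos(0, 0) == 1.0

    def test_slope_band_and_low_end_direction(self, default_healthy):
        res = eb.compare_workload_formulas(default_healthy)
        assert 0.8 < res["slope_kokkinos_on_ebm"] < 1.0
        assert res["ebm_higher_at_low_wl"]

    def test_slope_invariant_to_anthropometrics(self, small_healthy):
        res1 = eb.compare_workload_formulas(small_healthy)
        df = small_healthy.df.copy()
        df["mass_kg"] = df["mass_kg"] * 1.3
        df["height_m"] = np.minimum(df["height_m"] * 1.05, 2.2)
        df.pop("bmi")
        res2 = eb.compare_workload_formulas(eb.Cohort(df))
        assert res1["slope_kokkinos_on_ebm"] == pytest.approx(
            res2["slope_kokkinos_on_ebm"], abs=1e-12
        )


def test_slope_ci_matches_manual_formula():
    rng = np.random.default_rng(1)
    x = rng.uniform(1, 5, 12)
    y = 1.2 * x + rng.normal(0, 0.3, 12)
    b, se, half = _slope_ci(x, y)
    resid = y - b * x
    assert se == pytest.approx(
        np.sqrt(np.sum(resid**2) / 11 / np.sum(x**2)), abs=1e-12
    )
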