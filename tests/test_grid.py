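"""Analysis grid: cardinality, determinism, significance map, sensitivity runs."""

import numpy as np
import pandas as pd
import pytest

import aircrossover as ac
from aircrossover.grid import GridSpec, Subgroup


@pytest.fixture(scope="module")
def effect_simulation():
    """Three simulated years with a strong PM2.5 effect at lag 1.

    PM2.5 autocorrelation is kept low so the effect stays attributable to
    its true lag (a persistent exposure leaks significance into
    neighbouring lags, which is a property of the data, not a defect).
    """
    truth = ac.SimulationTruth(
        seed=21, phi=1.2, target_lag=1,
        pm25=ac.SeriesParams(6.8, 1.5, 196.0, 0.3, 4.3),
    )
    rng = np.random.default_rng(21)
    exposures = ac.simulate_exposures(truth, 1096, rng)
    iqr = ac.interquartile_range(exposures["pm25_ugm3"]).iqr
    truth.beta_per_unit = float(np.log(1.25) / iqr)
    visits = ac.simulate_counts(exposures, truth, rng)
    return exposures, visits


class TestRunGrid:
    def test_cell_cardinality(self, effect_simulation):
        exposures, visits = effect_simulation
        spec = GridSpec(subgroups=[Subgroup()], pollutants=("pm25",), lags=range(6))
        results = ac.run_grid(visits, exposures, spec)
        assert len(results) == 6
        assert (results["status"] == "ok").all()

    def test_deterministic_reruns_are_identical(self, effect_simulation, tmp_path):
        exposures, visits = effect_simulation
        spec = GridSpec(subgroups=[Subgroup(sex="M")], pollutants=("pm25",), lags=(0, 1))
        first = ac.run_grid(visits, exposures, spec)
        second = ac.run_grid(visits, exposures, spec)
        pd.testing.assert_frame_equal(first, second)
        ac.write_results(first, tmp_path / "a")
        ac.write_results(second, tmp_path / "b")
        assert (tmp_path / "a" / "results.csv").read_bytes() == (
            tmp_path / "b" / "results.csv"
        ).read_bytes()

    def test_effect_detected_at_the_simulated_lag(self, effect_simulation):
        exposures, visits = effect_simulation
        spec = GridSpec(subgroups=[Subgroup()], pollutants=("pm25",), lags=range(6))
        results = ac.run_grid(visits, exposures, spec).set_index("lag")
        assert results.loc[1, "rr_low"] > 1  # truth: effect at lag 1
        assert results.loc[5, "rr_low"] < 1 < results.loc[5, "rr_high"]

    def test_empty_subgroup_reported_not_fitted(self, effect_simulation):
        exposures, visits = effect_simulation
        none_visits = visits[visits["sex"] == "nobody"]
        spec = GridSpec(subgroups=[Subgroup(sex="M")], pollutants=("pm25",), lags=(0,))
        results = ac.run_grid(none_visits, exposures, spec)
        assert list(results["status"]) == ["empty_subgroup"]
        assert results["rr"].isna().all()

    def test_default_grid_covers_reporting_families(self):
        spec = GridSpec.default()
        labels = [s.label for s in spec.subgroups]
        assert "All" in labels and "M[8-12]" in labels and "mood:F" in labels
        assert len(labels) == 3 + 6 + 21


class TestSignificanceMap:
    def test_strict_lower_limit_rule(self):
        rows = []
        for lag, (lo, hi) in enumerate([(1.01, 1.10), (0.99, 1.05), (1.0, 1.2)]):
            rows.append(
                dict(subgroup="All", sex="A", age_group="all", category="all",
                     pollutant="no2", lag=lag, rr=(lo + hi) / 2, rr_low=lo, rr_high=hi,
                     status="ok")
            )
        results = pd.DataFrame(rows)
        sig = ac.significance_map(results)
        assert list(sig.loc[("All", "no2")]) == [1, 0, 0]  # exactly-1.0 bound is not flagged

    def test_failed_cells_count_as_zero(self):
        results = pd.DataFrame(
            [dict(subgroup="All", sex="A", age_group="all", category="all",
                  pollutant="no2", lag=0, rr=np.nan, rr_low=np.nan, rr_high=np.nan,
                  status="failed: x")]
        )
        assert ac.significance_map(results).values.sum() == 0

    def test_map_matches_estimates(self, effect_simulation):
        exposures, visits = effect_simulation
        spec = GridSpec(subgroups=[Subgroup(), Subgroup(sex="F")], pollutants=("pm25", "no2"),
                        lags=(0, 1))
        results = ac.run_grid(visits, exposures, spec)
        sig = ac.significance_map(results)
        for _, row in results.iterrows():
            expected = int(row["status"] == "ok" and row["rr_low"] > 1)
            assert sig.loc[(row["subgroup"], row["pollutant"]), row["lag"]] == expected


class TestSensitivitySplit:
    def test_halves_partition_and_compare(self, effect_simulation):
        exposures, visits = effect_simulation
        spec = GridSpec(subgroups=[Subgroup()], pollutants=("pm25",), lags=(1,))
        first, second, comparison = ac.sensitivity_split(
            visits, exposures, "2005-04-01", spec
        )
        assert first.loc[0, "n_days"] <= 366
        assert first.loc[0, "n_days"] + second.loc[0, "n_days"] <= len(exposures)
        assert {"beta_1", "beta_2", "z_diff"} <= set(comparison.columns)
        # constant simulated effect: halves should agree within sampling error
        assert abs(comparison.loc[0, "z_diff"]) < 4

    def test_cutpoint_outside_period_rejected(self, effect_simulation):
        exposures, visits = effect_simulation
        spec = GridSpec(subgroups=[Subgroup()], pollutants=("pm25",), lags=(1,))
        with pytest.raises(ValueError):
            ac.sensitivity_split(visits, exposures, "2030-01-01", spec)


class TestAqhiSensitivity:
    def test_aqhi_detects_a_pollutant_driven_effect(self):
        # counts driven strongly by NO2; the AQHI is monotone in NO2, so the
        # multi-pollutant index should pick the association up
        truth = ac.SimulationTruth(seed=31, phi=1.1, target_pollutant="no2", target_lag=1)
        rng = np.random.default_rng(31)
        exposures = ac.simulate_exposures(truth, 1096, rng)
        iqr = ac.interquartile_range(exposures["no2_ppb"]).iqr
        truth.beta_per_unit = float(np.log(1.3) / iqr)
        visits = ac.simulate_counts(exposures, truth, rng)
        spec = GridSpec(subgroups=[Subgroup()], pollutants=("pm25",), lags=(1,))
        aq = ac.aqhi_sensitivity(visits, exposures, spec)
        assert aq.loc[0, "pollutant"] == "aqhi"
        assert aq.loc[0, "rr_low"] > 1

    def test_constant_pollutants_make_aqhi_inestimable(self):
        truth = ac.SimulationTruth(
            no2=ac.SeriesParams(17.0, 0.0, 0.0, 0.0, 0.0),
            o3=ac.SeriesParams(33.0, 0.0, 0.0, 0.0, 0.0),
            pm25=ac.SeriesParams(7.0, 0.0, 0.0, 0.0, 0.0),
            temp=ac.SeriesParams(10.0, 2.0, 200.0, 0.5, 1.0),
            seed=5,
        )
        rng = np.random.default_rng(5)
        exposures = ac.simulate_exposures(truth, 365, rng)
        visits = ac.simulate_counts(exposures, truth, rng)
        spec = GridSpec(subgroups=[Subgroup()], pollutants=("pm25",), lags=(0,))
        aq = ac.aqhi_sensitivity(visits, exposures, spec)
        assert aq.loc[0, "status"].startswith("failed")

    def test_aqhi_iqr_on_calibrated_simulation(self):
        exposures = ac.simulate_exposures(ac.SimulationTruth(seed=6), 4292)
        iqr = ac.interquartile_range(exposures["aqhi"]).iqr
        assert 0.5 <= iqr <= 2.0


class TestWriteResults:
    def test_result_files_split_by_family(self, effect_simulation, tmp_path):
        exposures, visits = effect_simulation
        spec = GridSpec(
            subgroups=[Subgroup(), Subgroup(sex="M", age_group="13-18"), Subgroup(category="mood")],
            pollutants=("pm25",),
            lags=(1,),
        )
        results = ac.run_grid(visits, exposures, spec)
        paths = ac.write_results(results, tmp_path)
        assert pd.read_csv(paths["ResAll"])["subgroup"].tolist() == ["All"]
        assert pd.read_csv(paths["ResAgeGSex"])["subgroup"].tolist() == ["M[13-18]"]
        assert pd.read_csv(paths["ResTypeAMF"])["subgroup"].tolist() == ["mood:A"]
        assert paths["significance_map"].exists()
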