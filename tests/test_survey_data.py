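"""Detection histories, effort, independence filtering, survey arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import commoccu as co
from commoccu.survey_data import validate_records

from conftest import make_deployments, make_records

T0 = pd.Timestamp("2020-01-01 08:00")
DEP = make_deployments([("s1", "c1", "2020-01-01", "2020-03-01"),
                        ("s2", "c1", "2020-01-01", "2020-03-01"),
                        ("s3", "c2", "2020-01-01", "2020-03-01")])


class TestIndependenceFilter:
    @pytest.mark.parametrize("offsets_h,stations,expected", [
        # within the 24-h window at one station: suppressed
        ([0, 12], ["s1", "s1"], 1),
        # simultaneous records at different stations never suppress each other
        ([0, 0], ["s1", "s3"], 2),
        # greedy scan: third record is 1 h after the last *retained* one
        ([0, 25, 26], ["s1", "s1", "s1"], 2),
    ])
    def test_greedy_window(self, offsets_h, stations, expected):
        recs = make_records([(stn, "puma_concolor", T0 + pd.Timedelta(hours=h))
                             for h, stn in zip(offsets_h, stations)])
        out = co.filter_independent_records(recs)
        assert len(out) == expected

    def test_different_species_do_not_suppress(self):
        recs = make_records([("s1", "a", T0), ("s1", "b", T0)])
        assert len(co.filter_independent_records(recs)) == 2

    def test_record_outside_deployment_raises(self):
        recs = make_records([("s1", "a", "2019-12-01 10:00")])
        with pytest.raises(ValueError, match="outside any deployment"):
            co.filter_independent_records(recs, deployments=DEP)

    @given(st.lists(st.tuples(st.integers(0, 200), st.sampled_from("xy"),
                              st.sampled_from(["s1", "s3"])),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_matches_bruteforce(self, raw):
        recs = make_records([(stn, sp, T0 + pd.Timedelta(hours=h))
                             for h, sp, stn in raw])
        once = co.filter_independent_records(recs)
        twice = co.filter_independent_records(once)
        pd.testing.assert_frame_equal(once, twice)
        # brute-force greedy oracle per (species, station)
        window = pd.Timedelta(hours=24)
        expected = 0
        for (_, _), g in recs.sort_values("timestamp").groupby(
                ["species_code", "station_id"]):
            last = None
            for ts in g["timestamp"]:
                if last is None or ts - last >= window:
                    expected += 1
                    last = ts
        assert len(once) == expected


class TestDetectionHistories:
    def grid(self):
        return co.SurveyGrid(("c1", "c2"), {"c1": "A", "c2": "A"})

    def test_pooled_detection_sets_one(self):
        recs = make_records([("s2", "a", "2020-01-16 03:00")])  # week 3 (k=2)
        t = co.build_detection_histories(recs, DEP, self.grid(),
                                         species=("a",))
        assert t.y[0, 0, 2] == 1.0
        assert t.y[0, 0, 0] == 0.0

    def test_zero_effort_is_na_and_active_no_record_is_zero(self):
        dep = make_deployments([("s1", "c1", "2020-01-01", "2020-01-07"),
                                ("s3", "c2", "2020-01-01", "2020-01-21")])
        recs = make_records([("s1", "a", "2020-01-02 12:00")])
        t = co.build_detection_histories(recs, dep, self.grid(),
                                         species=("a",))
        assert np.isnan(t.y[0, 0, 1])       # c1 camera inactive in week 2
        assert t.y[0, 1, 1] == 0.0          # c2 active, no record
        # duality enforced structurally
        assert np.array_equal(np.isnan(t.y[0]), t.effort.effort == 0)

    def test_unknown_species_raises(self):
        recs = make_records([("s1", "mystery", "2020-01-02 12:00")])
        with pytest.raises(ValueError):
            co.build_detection_histories(recs, DEP, self.grid(),
                                         species=("a",))

    def test_adding_record_never_unsets_detection(self, toy_dataset):
        ds = toy_dataset
        t1, _ = ds.to_tensor()
        extra = ds.records.iloc[[0]].copy()
        extra["timestamp"] = extra["timestamp"] + pd.Timedelta(hours=1)
        recs = pd.concat([ds.records, extra], ignore_index=True)
        t2 = co.build_detection_histories(
            recs, ds.deployments, ds.grid(),
            species=tuple(ds.species["species_code"]))
        was_one = t1.y == 1
        assert (t2.y[was_one] == 1).all()


class TestEffort:
    def test_trap_night_sums(self):
        dep = make_deployments([("s1", "c1", "2020-01-01", "2020-01-07"),
                                ("s2", "c1", "2020-01-01", "2020-01-03"),
                                ("s3", "c2", "2020-01-01", "2020-01-14")])
        grid = co.SurveyGrid(("c1", "c2"), {"c1": "A", "c2": "A"})
        eff = co.build_effort(dep, grid)
        assert eff.effort[0, 0] == 10        # 7 + 3 nights in week 1
        assert eff.effort[0, 1] == 0         # c1 cameras both off in week 2
        assert eff.effort[1, 0] == 7 and eff.effort[1, 1] == 7

    def test_standardized_mean_zero(self, toy_dataset):
        eff = co.build_effort(toy_dataset.deployments, toy_dataset.grid())
        pos = eff.effort > 0
        assert abs(eff.effort_std[pos].mean()) < 1e-9
        assert abs(eff.effort_std[pos].std() - 1) < 1e-9


class TestDetectionRate:
    def test_rates_match_hand_computation(self):
        dep = make_deployments([
            ("s1", "c1", "2020-01-01", "2020-04-09"),   # 100 nights
            ("s2", "c1", "2020-01-01", "2020-05-29"),   # 150 nights
            ("s3", "c2", "2020-01-01", "2020-02-19"),   # 50 nights
            ("s4", "c3", "2020-01-01", "2020-01-20"),   # 20 nights
        ])
        grid = co.SurveyGrid(("c1", "c2", "c3"),
                             {c: "A" for c in ("c1", "c2", "c3")})
        recs = make_records(
            [("s1", "homo_sapiens", f"2020-01-{d:02d} 10:00")
             for d in range(1, 6)]
            + [("s3", "homo_sapiens", "2020-01-10 10:00")])
        rate = co.detection_rate_covariate(recs, dep, grid, "homo_sapiens")
        assert rate["c1"] == pytest.approx(5 / 250 * 1000)   # 20 per 1,000
        assert rate["c2"] == pytest.approx(1 / 50 * 1000)
        assert rate["c3"] == 0.0

    def test_zero_trap_nights_gives_na(self):
        dep = make_deployments([("s1", "c1", "2020-01-01", "2020-01-10")])
        grid = co.SurveyGrid(("c1", "c2"), {"c1": "A", "c2": "A"})
        with pytest.warns(UserWarning, match="zero trap nights"):
            rate = co.detection_rate_covariate(make_records([]), dep, grid,
                                               "homo_sapiens")
        assert np.isnan(rate["c2"])


class TestSurveySummary:
    def test_coverage_and_area(self):
        dep = make_deployments([(f"s{j}", f"c{j}", "2020-01-01", "2020-01-10")
                                for j in range(55)])
        cells = tuple(f"c{j}" for j in range(63))
        grid = co.SurveyGrid(cells, {f"c{j}": "A" for j in range(55)})
        s = co.survey_summary(dep, grid)
        assert s.percent_surveyed == 87.30
        assert s.surveyed_area_km2 == 880.0
        assert s.n_stations == 55
        assert s.total_trap_nights == 55 * 10

    def test_empty_survey(self):
        grid = co.SurveyGrid(("c1",), {})
        s = co.survey_summary(make_deployments([]), grid)
        assert s.percent_surveyed == 0.0 and s.surveyed_area_km2 == 0.0


class TestCovariates:
    def test_standardization_round_trip(self, toy_dataset):
        cov = co.standardize_covariates(toy_dataset.covariates)
        assert np.allclose(cov.unstandardize(), cov.D, atol=1e-10)
        assert np.allclose(cov.D_std.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(cov.D_std.std(axis=0), 1, atol=1e-12)

    def test_correlation_matrix_shape(self, toy_dataset):
        cov = co.standardize_covariates(toy_dataset.covariates)
        c = cov.correlations.to_numpy()
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)


def test_record_validation_respects_intervals():
    recs = make_records([("s1", "a", "2020-01-05 10:00")])
    validate_records(recs, DEP)  # inside: fine
    with pytest.raises(ValueError):
        validate_records(make_records([("s9", "a", "2020-01-05 10:00")]), DEP)
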