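"""Curation of source-apportionment records: reading, filtering, design."""

import numpy as np
import pandas as pd
import pytest

import trafficpm as tp
from trafficpm.records import DEFAULT_REGRESSORS, LOCATION_CATEGORIES


def _rows(n=3, **overrides):
    base = {
        "study_id": "S1", "city": "Testville", "country": "Spain",
        "region": "Southwestern Europe", "pub_year": 2010, "population": 1_000_000,
        "latitude": 40.0, "longitude": -3.0, "site_type": "urban",
        "overall_pm25": 20.0, "traffic_share_pct": 25.0,
        "sea_salt_reported": 1, "method": "PMF",
    }
    rows = []
    for i in range(n):
        row = dict(base)
        row["study_id"] = f"S{i}"
        for key, vals in overrides.items():
            row[key] = vals[i] if isinstance(vals, (list, tuple)) else vals
        rows.append(row)
    return pd.DataFrame(rows)


def _write(df, tmp_path, name="records.csv"):
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


class TestReadRecords:
    def test_well_formed_rows_round_trip(self, tmp_path):
        path = _write(_rows(3), tmp_path)
        out = tp.read_records(path)
        assert len(out) == 3
        assert out.loc[0, "overall_pm25"] == 20.0

    def test_dialect_maps_foreign_headers(self, tmp_path):
        df = _rows(2).rename(columns={"overall_pm25": "PM25_total"})
        path = _write(df, tmp_path)
        out = tp.read_records(path, dialect={"overall_pm25": "PM25_total"})
        assert len(out) == 2

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = _write(_rows(2).drop(columns=["latitude"]), tmp_path)
        with pytest.raises(tp.ConfigurationError, match="latitude"):
            tp.read_records(path)

    def test_empty_file_is_data_error(self, tmp_path):
        path = _write(_rows(0), tmp_path)
        with pytest.raises(tp.DataError):
            tp.read_records(path)

    @pytest.mark.parametrize("column,value,fragment", [
        ("overall_pm25", -4, "overall_pm25"),
        ("overall_pm25", "−4", "unparseable"),  # unicode minus cannot parse
        ("latitude", 120.0, "latitude"),
        ("traffic_share_pct", 0.0, "traffic_share_pct"),
        ("traffic_share_pct", 150.0, "traffic_share_pct"),
        ("pub_year", 1950, "pub_year"),
    ])
    def test_invalid_rows_reported_with_row_number(self, tmp_path, column, value, fragment):
        df = _rows(3)
        df[column] = df[column].astype(object)
        df.loc[1, column] = value
        path = _write(df, tmp_path)
        with pytest.raises(tp.ValidationError) as exc:
            tp.read_records(path)
        assert any("row 1" in p and fragment in p for p in exc.value.problems)

    def test_missing_traffic_share_allowed(self, tmp_path):
        df = _rows(2, traffic_share_pct=[25.0, None])
        path = _write(df, tmp_path)
        out = tp.read_records(path)
        assert out["traffic_share_pct"].isna().sum() == 1

    def test_packaged_paper_scale_fixture(self, paper_fixture):
        records, truth = paper_fixture
        assert len(records) == 182
        assert records["city"].nunique() == truth["n_cities"] == 117


class TestFilterRecords:
    def test_each_rule_removes_one(self):
        df = _rows(3, site_type=["urban", "industrial", "urban"],
                   traffic_share_pct=[25.0, 25.0, np.nan])
        kept, log = tp.filter_records(df)
        assert len(kept) == 1
        assert log["n_removed_non_urban"] == 1
        assert log["n_removed_no_traffic_share"] == 1

    def test_identity_on_clean_input(self):
        df = _rows(4)
        kept, log = tp.filter_records(df)
        assert len(kept) == 4 and log["n_retained"] == 4

    def test_idempotent(self):
        df = _rows(5, site_type=["urban", "rural", "urban", "urban", "industrial"])
        once, _ = tp.filter_records(df)
        twice, _ = tp.filter_records(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_all_filtered_is_data_error(self):
        with pytest.raises(tp.DataError):
            tp.filter_records(_rows(2, site_type="rural"))

    def test_contaminated_fixture_recount(self):
        cfg = tp.GeneratorConfig(n_obs=120, n_cities=60, nonurban_frac=0.1,
                                 missing_share_frac=0.1, seed=7)
        df, _ = tp.simulate_dataset(cfg)
        share = pd.to_numeric(df["traffic_share_pct"], errors="coerce")
        expected = int(((df["site_type"] == "urban") & share.notna()).sum())
        kept, _ = tp.filter_records(df.assign(traffic_share_pct=share))
        assert len(kept) == expected


class TestCurate:
    def test_traffic_concentration_arithmetic(self):
        curated, _ = tp.curate(_rows(1, overall_pm25=20.0, traffic_share_pct=25.0))
        assert curated.loc[0, "traffic_pm25"] == pytest.approx(5.0)

    def test_published_after_cut_boundary(self):
        curated, _ = tp.curate(_rows(2, pub_year=[2005, 2006]))
        assert curated["post2005"].tolist() == [0, 1]

    def test_japan_grouped_with_north_america_oceania(self):
        curated, _ = tp.curate(_rows(1, country="Japan", region="East Asia"))
        assert curated.loc[0, "loc_cat"] == "NA_Oceania_Japan"

    @pytest.mark.parametrize("region,expected", [
        ("North America", "NA_Oceania_Japan"),
        ("Oceania/Japan", "NA_Oceania_Japan"),
        ("Western Europe", "NW_W_Europe"),
        ("Northwestern Europe", "NW_W_Europe"),
        ("Southwestern Europe", "rest_of_Europe"),
        ("Central and Eastern Europe", "rest_of_Europe"),
        ("Southern Asia", "rest_of_world"),
    ])
    def test_location_grouping(self, region, expected):
        curated, _ = tp.curate(_rows(1, region=region))
        assert curated.loc[0, "loc_cat"] == expected

    def test_population_scaling_and_latitude(self):
        curated, _ = tp.curate(_rows(1, population=2_000_000, latitude=30.0))
        assert curated.loc[0, "ln_population"] == pytest.approx(np.log(2.0))
        assert curated.loc[0, "lat10"] == pytest.approx(3.0)

    def test_zero_share_rejected_with_reason(self):
        df = _rows(2, traffic_share_pct=[25.0, 0.0])
        curated, log = tp.curate(df)
        assert len(curated) == 1
        assert log["n_dropped"] == 1
        assert "ln undefined" in log["dropped"][0]["reason"]

    def test_nonpositive_population_is_validation_error(self):
        with pytest.raises(tp.ValidationError):
            tp.curate(_rows(1, population=0))

    def test_missing_population_complete_case(self):
        df = _rows(2, population=[1e6, np.nan])
        curated, log = tp.curate(df)
        assert len(curated) == 1 and log["n_dropped"] == 1

    def test_traffic_never_exceeds_overall(self, curated_paper):
        assert (curated_paper["traffic_pm25"] > 0).all()
        assert (curated_paper["traffic_pm25"] <= curated_paper["overall_pm25"]).all()


class TestBuildDesign:
    def test_default_column_sets(self, curated_paper):
        dm = tp.build_design(curated_paper)
        assert dm.X1.shape[1] == 6 and dm.X2.shape[1] == 6
        assert "post2005" in dm.x1_names and "post2005" not in dm.x2_names
        assert "loc_rest_of_Europe" in dm.x2_names and "loc_rest_of_Europe" not in dm.x1_names

    def test_outcomes_are_logs(self, curated_paper):
        dm = tp.build_design(curated_paper)
        np.testing.assert_allclose(dm.y1, np.log(curated_paper["traffic_pm25"]))
        np.testing.assert_allclose(dm.y2, np.log(curated_paper["overall_pm25"]))

    def test_single_record_latitude_scaling(self):
        curated, _ = tp.curate(_rows(1, latitude=30.0))
        dm = tp.build_design(curated)
        assert dm.X1[0, dm.x1_names.index("lat10")] == pytest.approx(3.0)

    def test_location_dummies_mutually_exclusive(self, curated_paper):
        dm = tp.build_design(curated_paper)
        loc_cols = [i for i, n in enumerate(dm.x2_names) if n.startswith("loc_")]
        assert (dm.X2[:, loc_cols].sum(axis=1) <= 1).all()

    def test_unknown_regressor_is_configuration_error(self, curated_paper):
        cfg = {"traffic": ["ln_population", "altitude"], "overall": ["ln_population"]}
        with pytest.raises(tp.ConfigurationError, match="altitude"):
            tp.build_design(curated_paper, cfg)

    def test_row_permutation_permutes_design(self, curated_paper, rng):
        dm = tp.build_design(curated_paper)
        perm = rng.permutation(len(curated_paper))
        dm_p = tp.build_design(curated_paper.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(dm_p.y1, dm.y1[perm])
        np.testing.assert_allclose(dm_p.X2, dm.X2[perm])


class TestDescriptiveSummary:
    def test_two_record_moments(self):
        curated, _ = tp.curate(_rows(2, overall_pm25=[10.0, 30.0]))
        conc = tp.descriptive_summary(curated)["concentrations"]
        assert conc.loc["overall_pm25", "mean"] == pytest.approx(20.0)
        assert conc.loc["overall_pm25", "min"] == pytest.approx(10.0)
        assert conc.loc["overall_pm25", "max"] == pytest.approx(30.0)

    def test_single_region_is_100_percent(self):
        curated, _ = tp.curate(_rows(3, region="East Asia"))
        regions = tp.descriptive_summary(curated)["regions"]
        assert regions.loc["East Asia", "percent"] == pytest.approx(100.0)

    def test_region_percents_sum_to_100(self, curated_paper):
        regions = tp.descriptive_summary(curated_paper)["regions"]
        assert regions["percent"].sum() == pytest.approx(100.0, abs=0.01)

    def test_matches_independent_recomputation(self, curated_paper):
        summary = tp.descriptive_summary(curated_paper)
        x = curated_paper["ln_population"].to_numpy()
        assert summary["covariates"].loc["ln_population", "mean"] == pytest.approx(x.mean())
        assert summary["covariates"].loc["ln_population", "sd"] == pytest.approx(
            x.std(ddof=1))
        t = curated_paper["traffic_pm25"].to_numpy()
        assert summary["concentrations"].loc["traffic_pm25", "max"] == pytest.approx(t.max())
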